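"""Published measurement tables used as simulation inputs and oracles.

``COMPOSITIONS`` holds the measured subpopulation percentages (of all
acquired events) for three lactic-acid-bacteria strains under six
culturing / drying treatments.  The four categories never sum to 100%;
the remainder corresponds to events removed by the gating chain
(non-cellular debris, aggregates, out-of-focus images) and is modelled
as such by :func:`ifcgate.synthetic_data.mixture_from_percentages`.

``PLATE_COUNTS`` and ``FLOW_COUNTS`` hold the published enumeration
results (cfu/mL from pour plates, obj/mL from cytometry), and
``SORTING_GROWTH`` the post-sort growth fractions (out of 24 sorted
single cells per subpopulation and medium, at 48 h and 72 h).
"""

from __future__ import annotations

# Percent of all events: (active, mid_active_1, mid_active_2, dead)
COMPOSITIONS: dict[tuple[str, str], dict[str, float]] = {
    ("e_faecium", "control"): dict(active=62.9, mid_active_1=0.84, mid_active_2=17.93, dead=9.15),
    ("l_mesenteroides", "control"): dict(active=77.5, mid_active_1=0.39, mid_active_2=6.21, dead=8.02),
    ("c_divergens", "control"): dict(active=69.7, mid_active_1=0.21, mid_active_2=15.35, dead=8.07),
    ("e_faecium", "heat_shock"): dict(active=63.79, mid_active_1=0.09, mid_active_2=21.60, dead=6.12),
    ("l_mesenteroides", "heat_shock"): dict(active=25.23, mid_active_1=1.03, mid_active_2=33.86, dead=26.5),
    ("c_divergens", "heat_shock"): dict(active=57.87, mid_active_1=0.41, mid_active_2=21.46, dead=10.50),
    ("e_faecium", "ph_shock"): dict(active=3.17, mid_active_1=2.06, mid_active_2=16.54, dead=71.68),
    ("l_mesenteroides", "ph_shock"): dict(active=3.04, mid_active_1=1.03, mid_active_2=8.47, dead=83.86),
    ("c_divergens", "ph_shock"): dict(active=9.08, mid_active_1=6.63, mid_active_2=11.49, dead=65.05),
    ("e_faecium", "uncontrolled_ph"): dict(active=32.22, mid_active_1=14.22, mid_active_2=11.08, dead=34.59),
    ("l_mesenteroides", "uncontrolled_ph"): dict(active=32.32, mid_active_1=6.15, mid_active_2=20.58, dead=34.25),
    ("c_divergens", "uncontrolled_ph"): dict(active=29.85, mid_active_1=17.79, mid_active_2=11.02, dead=32.88),
    ("e_faecium", "dried"): dict(active=36.31, mid_active_1=0.69, mid_active_2=41.77, dead=6.49),
    ("l_mesenteroides", "dried"): dict(active=33.23, mid_active_1=0.41, mid_active_2=44.61, dead=10.42),
    ("c_divergens", "dried"): dict(active=34.78, mid_active_1=0.68, mid_active_2=39.45, dead=9.22),
    ("e_faecium", "coated"): dict(active=0.99, mid_active_1=11.71, mid_active_2=8.67, dead=73.53),
    ("l_mesenteroides", "coated"): dict(active=0.43, mid_active_1=7.63, mid_active_2=1.94, dead=87.05),
    ("c_divergens", "coated"): dict(active=0.32, mid_active_1=6.18, mid_active_2=1.26, dead=90.06),
}

# Plate cell counts, cfu/mL
PLATE_COUNTS: dict[tuple[str, str], float] = {
    ("l_mesenteroides", "control"): 2.7e8,
    ("l_mesenteroides", "heat_shock"): 1.29e8,
    ("e_faecium", "control"): 4.05e8,
    ("e_faecium", "heat_shock"): 5.85e8,
    ("c_divergens", "control"): 4.05e8,
    ("c_divergens", "heat_shock"): 9.35e7,
}

# Flow cytometric enumeration, obj/mL: total and per subpopulation
FLOW_COUNTS: dict[tuple[str, str], dict[str, float]] = {
    ("l_mesenteroides", "control"): dict(
        total=3.57e8, dead=2.16e7, mid_active_1=1.05e6, mid_active_2=1.68e7, active=2.10e8),
    ("l_mesenteroides", "heat_shock"): dict(
        total=1.85e8, dead=3.52e7, mid_active_1=1.36e6, mid_active_2=4.50e7, active=3.35e7),
    ("e_faecium", "control"): dict(
        total=2.72e8, dead=2.17e7, mid_active_1=2.02e5, mid_active_2=4.26e7, active=1.47e8),
    ("e_faecium", "heat_shock"): dict(
        total=2.53e8, dead=1.32e7, mid_active_1=2.04e5, mid_active_2=4.65e7, active=1.37e8),
    ("c_divergens", "control"): dict(
        total=3.40e8, dead=2.13e7, mid_active_1=5.68e5, mid_active_2=4.05e7, active=1.84e8),
    ("c_divergens", "heat_shock"): dict(
        total=2.50e8, dead=2.13e7, mid_active_1=8.37e5, mid_active_2=4.36e7, active=1.18e8),
}

# Post-sort growth: {(strain, treatment): {medium: {subpop: (k48, k72)}}}
# counts out of 24 sorted single cells (agar = colonies on MRS-Agar,
# broth = wells with blank-subtracted OD600 > 0.1 in MRS broth).
SORTING_GROWTH: dict[tuple[str, str], dict[str, dict[str, tuple[int, int]]]] = {
    ("e_faecium", "dried"): {
        "agar": dict(active=(5, 9), mid_active_1=(0, 0), mid_active_2=(2, 2), dead=(0, 0)),
        "broth": dict(active=(18, 20), mid_active_1=(0, 0), mid_active_2=(2, 4), dead=(0, 0)),
    },
    ("e_faecium", "coated"): {
        "agar": dict(active=(5, 7), mid_active_1=(0, 0), mid_active_2=(6, 7), dead=(0, 0)),
        "broth": dict(active=(5, 7), mid_active_1=(0, 0), mid_active_2=(3, 3), dead=(0, 0)),
    },
    ("l_mesenteroides", "dried"): {
        "agar": dict(active=(1, 2), mid_active_1=(0, 0), mid_active_2=(2, 2), dead=(0, 0)),
        "broth": dict(active=(1, 2), mid_active_1=(0, 0), mid_active_2=(0, 0), dead=(0, 0)),
    },
    ("l_mesenteroides", "coated"): {
        "agar": dict(active=(5, 8), mid_active_1=(0, 0), mid_active_2=(1, 3), dead=(0, 0)),
        "broth": dict(active=(2, 5), mid_active_1=(1, 3), mid_active_2=(1, 1), dead=(0, 1)),
    },
}

N_SORTED_CELLS = 24
OD600_GROWTH_THRESHOLD = 0.1
COLONY_COUNT_RANGE = (30, 300)
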