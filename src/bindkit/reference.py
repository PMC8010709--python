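"""Literature-reported constants for CBM-cellulose binding to cellulose I
and III.

These values — equilibrium adsorption parameters for GFP-CBM1 and
GFP-CBM3a on Cladophora-derived cellulose, truncation-sensitivity refits,
QCM-D kinetic constants, single-molecule motility statistics, rupture
lifetime summaries, and XRD peak positions — serve two purposes: they are
the default "truth" parameter sets for the synthetic-data generators, and
they are the printed inputs from which the headline substrate deltas
(velocity reduction, commitment reduction, affinity fold changes) are
recomputed as worked examples.

Units: K_d in uM, n_max in umol protein / g cellulose, rates in s^-1,
velocities in nm/s, forces in pN, lifetimes in s, angles in degrees 2-theta.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Equilibrium adsorption (pull-down assays), GFP-CBM1
# ---------------------------------------------------------------------------

CBM1_ISOTHERM = {
    "cellulose_I": {
        "one_site": {"n_max": 4.34, "K_d": 8.69},
        "two_site": {"n_max": 4.14, "K_d": 13.68, "n_max_2": 0.42, "K_d_2": 0.13},
        "langmuir_freundlich": {"n_max": 4.80, "K_d": 6.90, "m": 0.77},
    },
    "cellulose_III": {
        "one_site": {"n_max": 3.32, "K_d": 10.55},
        "two_site": {"n_max": 2.81, "K_d": 25.06, "n_max_2": 0.75, "K_d_2": 0.92},
        "langmuir_freundlich": {"n_max": 3.82, "K_d": 7.77, "m": 0.73},
    },
}

# One-site refits of the cellulose datasets truncated at 50 and 15 uM free
# protein (full-dataset values repeated for convenience)
CBM1_TRUNCATION = {
    "cellulose_I": {
        "full": {"n_max": 4.34, "K_d": 8.69},
        "50uM": {"n_max": 3.95, "K_d": 7.05},
        "15uM": {"n_max": 3.18, "K_d": 4.68},
    },
    "cellulose_III": {
        "full": {"n_max": 3.32, "K_d": 10.55},
        "50uM": {"n_max": 3.23, "K_d": 9.88},
        "15uM": {"n_max": 1.82, "K_d": 2.91},
    },
}

CBM3A_ISOTHERM = {
    "cellulose_I": {
        "one_site": {"n_max": 2.36, "K_d": 2.15},
        "two_site": {"n_max": 1.81, "K_d": 16.64, "n_max_2": 0.99, "K_d_2": 0.28},
        "langmuir_freundlich": {"n_max": 3.21, "K_d": 2.61, "m": 0.53},
    },
    "cellulose_III": {
        "one_site": {"n_max": 1.48, "K_d": 6.15},
        "two_site": {"n_max": 3.66, "K_d": 227.30, "n_max_2": 0.67, "K_d_2": 0.64},
        "langmuir_freundlich": {"n_max": 7.58, "K_d": 19.10, "m": 0.42},
    },
}

# ---------------------------------------------------------------------------
# QCM-D Langmuir kinetics, GFP-CBM3a on nanocrystalline cellulose
# A in bound molecules at saturation (reported scale), rates in s^-1
# ---------------------------------------------------------------------------

CBM3A_QCMD = {
    "cellulose_I": {"A": 145.55e12, "k_on_star": 0.13, "k_off": 4.60e-3},
    "cellulose_III": {"A": 97.71e12, "k_on_star": 0.14, "k_off": 11.30e-3},
}

# FRAP desorption-rate fold change (cellulose III vs I) for GFP-CBM3a
CBM3A_FRAP_KOFF_FOLD = 1.9

# ---------------------------------------------------------------------------
# Single-molecule Cel7A motility
# ---------------------------------------------------------------------------

CEL7A_MOTILITY = {
    "cellulose_I": {
        "velocity": 0.25,  # nm/s (SD 0.35, N = 68 traces)
        "velocity_sd": 0.35,
        "n_traces": 68,
        "dwell_tau": 0.75,  # s
        "reverse_fraction": 0.35,
        "instability_n_unstable": 2,  # 12% of N = 17
        "instability_n": 17,
        "instability_printed_pct": 12.0,
    },
    "cellulose_III": {
        "velocity": 0.17,
        "velocity_sd": 0.14,
        "n_traces": 30,
        "dwell_tau": 0.92,
        "reverse_fraction": 0.39,
        "instability_n_unstable": 3,  # 23% of N = 13
        "instability_n": 13,
        "instability_printed_pct": 23.0,
    },
}

# ---------------------------------------------------------------------------
# Single-bond CBM1 rupture lifetimes (all forces pooled)
# ---------------------------------------------------------------------------

CBM1_RUPTURE = {
    "cellulose_I": {"mean": 1.41, "sd": 4.12, "n": 410},
    "cellulose_III": {"mean": 1.11, "sd": 1.82, "n": 214},
}

# ---------------------------------------------------------------------------
# XRD: equatorial reflection positions (degrees 2-theta)
# ---------------------------------------------------------------------------

XRD_PEAKS = {
    "cellulose_I": (14.9, 17.1, 23.0),
    "cellulose_III": (11.8, 17.4, 20.9),
}
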