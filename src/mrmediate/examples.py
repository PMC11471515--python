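"""Published reference estimates used by the worked examples and tests.

These are summary-level results from a two-sample MR screen of blood
metabolites and inflammatory cytokines against venous thromboembolism
endpoints (VTE, DVT, PE): the IVW estimates for the PDGF-BB legs, the
two-step triplets for the glycocholate and dodecanedioate (C12:1-DC)
pathways, and the MVMR-adjusted mediator effects.  They serve as *inputs* to
the mediation calculus — the package's arithmetic can be checked against the
mediated effects the source analysis reported.
"""

from __future__ import annotations

#: IVW estimates (beta, se, p) of PDGF-BB on each endpoint, 12 instruments
PDGF_BB_IVW = {
    "VTE": {"beta": 0.103, "se": 0.026, "pval": 9.29e-5, "n_snp": 12},
    "DVT": {"beta": 0.192, "se": 0.048, "pval": 5.66e-5, "n_snp": 12},
    "PE": {"beta": 0.087, "se": 0.036, "pval": 1.53e-2, "n_snp": 12},
}

#: the cytokine panel size (BH-FDR family for the cytokine screen)
CYTOKINE_PANEL_SIZE = 41

#: two-step triplets: (exposure, outcome) -> the three univariable IVW legs
TWO_STEP_TRIPLETS = {
    ("glycocholate", "VTE"): {
        "beta_em": -0.097, "se_em": 0.036, "p_em": 7.44e-3,
        "beta_mo": 0.103, "se_mo": 0.026, "p_mo": 9.29e-5,
        "beta_eo": -0.059, "se_eo": 0.021, "p_eo": 5.60e-3,
    },
    ("dodecanedioate", "VTE"): {
        "beta_em": 0.096, "se_em": 0.048, "p_em": 4.49e-2,
        "beta_mo": 0.103, "se_mo": 0.026, "p_mo": 9.29e-5,
        "beta_eo": 0.068, "se_eo": 0.028, "p_eo": 1.61e-2,
    },
    ("glycocholate", "DVT"): {
        "beta_em": -0.097, "se_em": 0.036, "p_em": 7.44e-3,
        "beta_mo": 0.192, "se_mo": 0.048, "p_mo": 5.66e-5,
        "beta_eo": -0.106, "se_eo": 0.038, "p_eo": 4.90e-3,
    },
    ("dodecanedioate", "DVT"): {
        "beta_em": 0.096, "se_em": 0.048, "p_em": 4.49e-2,
        "beta_mo": 0.192, "se_mo": 0.048, "p_mo": 5.66e-5,
        "beta_eo": 0.137, "se_eo": 0.052, "p_eo": 8.60e-3,
    },
    ("glycocholate", "PE"): {
        "beta_em": -0.097, "se_em": 0.036, "p_em": 7.44e-3,
        "beta_mo": 0.087, "se_mo": 0.036, "p_mo": 1.53e-2,
        "beta_eo": -0.071, "se_eo": 0.030, "p_eo": 2.03e-2,
    },
}

#: MVMR rows: exposure beta_EM, the adjusted mediator effect beta'_MO with
#: its 95% CI, the direct exposure effect beta'_EO, and the total beta_EO
MVMR_ROWS = {
    ("glycocholate", "VTE"): {
        "beta_em": -0.097, "se_em": 0.036,
        "beta_prime_mo": 0.089, "ci_prime_mo": (0.041, 0.136),
        "beta_prime_eo": -0.026, "beta_eo": -0.059,
    },
    ("dodecanedioate", "VTE"): {
        "beta_em": 0.096, "se_em": 0.048,
        "beta_prime_mo": 0.090, "ci_prime_mo": (0.039, 0.142),
        "beta_prime_eo": -0.019, "beta_eo": 0.068,
    },
    ("glycocholate", "DVT"): {
        "beta_em": -0.097, "se_em": 0.036,
        "beta_prime_mo": 0.187, "ci_prime_mo": (0.098, 0.276),
        "beta_prime_eo": 0.003, "beta_eo": -0.106,
    },
    ("dodecanedioate", "DVT"): {
        "beta_em": 0.096, "se_em": 0.048,
        "beta_prime_mo": 0.174, "ci_prime_mo": (0.082, 0.266),
        "beta_prime_eo": -0.008, "beta_eo": 0.137,
    },
    ("glycocholate", "PE"): {
        "beta_em": -0.097, "se_em": 0.036,
        "beta_prime_mo": 0.076, "ci_prime_mo": (0.015, 0.136),
        "beta_prime_eo": -0.048, "beta_eo": -0.071,
    },
}

#: mediated effects (3-decimal) the source analysis reported for the same rows
REPORTED_MEDIATED_EFFECTS = {
    ("glycocholate", "VTE"): -0.009,
    ("dodecanedioate", "VTE"): 0.009,
    ("glycocholate", "DVT"): -0.018,
    ("dodecanedioate", "DVT"): 0.017,
    ("glycocholate", "PE"): -0.007,
}
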