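"""Published mixed-logit estimates for the orphan-drug reimbursement DCE.

These are the printed preference coefficients from the published
orphan-drug value study (69 valid respondents: 37 health-economics
experts and 32 basic-medical-insurance experts), used as inputs for
weight derivation and as the mean part-worths of the synthetic
respondent population.  Coefficients are printed to three decimals;
log-likelihoods to five.

Index order matches ``AttributeSchema.design_columns`` of the default
schema, i.e. severity_1, severity_2, unmet_1, unmet_2, efficacy_1,
efficacy_2, hrqol_1, hrqol_2, safety_1, safety_2, evidence_1,
evidence_2, cost_10k; the opt-out alternative-specific constant is kept
separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ("all", "health-economics", "medical-insurance")

GROUP_SIZES = {"all": 69, "health-economics": 37, "medical-insurance": 32}

#: scored tasks per respondent entering estimation (repeat excluded)
SCORED_TASKS = 10
#: alternatives per task (drug 1, drug 2, opt-out)
N_ALTERNATIVES = 3

DESIGN_COLUMNS = [
    "severity_1",
    "severity_2",
    "unmet_1",
    "unmet_2",
    "efficacy_1",
    "efficacy_2",
    "hrqol_1",
    "hrqol_2",
    "safety_1",
    "safety_2",
    "evidence_1",
    "evidence_2",
    "cost_10k",
]

_COEF = {
    "all": {
        "asc_opt_out": (2.454, 0.506),
        "cost_10k": (-0.039, 0.006),
        "severity_1": (1.509, 0.303),
        "severity_2": (1.753, 0.313),
        "unmet_1": (-0.072, 0.210),
        "unmet_2": (0.361, 0.281),
        "efficacy_1": (0.531, 0.245),
        "efficacy_2": (1.120, 0.227),
        "hrqol_1": (1.610, 0.309),
        "hrqol_2": (2.204, 0.330),
        "safety_1": (1.037, 0.280),
        "safety_2": (1.231, 0.279),
        "evidence_1": (1.028, 0.240),
        "evidence_2": (0.676, 0.256),
    },
    "health-economics": {
        "asc_opt_out": (5.363, 1.247),
        "cost_10k": (-0.067, 0.017),
        "severity_1": (2.936, 0.731),
        "severity_2": (3.877, 0.851),
        "unmet_1": (0.614, 0.345),
        "unmet_2": (1.917, 0.543),
        "efficacy_1": (0.888, 0.432),
        "efficacy_2": (2.354, 0.697),
        "hrqol_1": (2.359, 0.561),
        "hrqol_2": (3.995, 1.042),
        "safety_1": (1.178, 0.462),
        "safety_2": (1.011, 0.435),
        "evidence_1": (0.906, 0.379),
        "evidence_2": (1.061, 0.521),
    },
    "medical-insurance": {
        "asc_opt_out": (1.939, 0.947),
        "cost_10k": (-0.053, 0.016),
        "severity_1": (1.428, 0.544),
        "severity_2": (1.296, 0.574),
        "unmet_1": (-0.577, 0.361),
        "unmet_2": (-1.017, 0.523),
        "efficacy_1": (0.590, 0.450),
        "efficacy_2": (1.054, 0.429),
        "hrqol_1": (2.047, 0.690),
        "hrqol_2": (2.433, 0.666),
        "safety_1": (1.512, 0.562),
        "safety_2": (2.355, 0.774),
        "evidence_1": (1.594, 0.462),
        "evidence_2": (0.808, 0.417),
    },
}

LOG_LIKELIHOOD = {
    "all": -575.88767,
    "health-economics": -281.83149,
    "medical-insurance": -254.76378,
}

#: 14 utility means (13 design coefficients + opt-out ASC) + 12 random SDs
#: (the twelve categorical dummies random, cost and ASC fixed)
N_PARAMETERS = 26


def published_means(group: str = "all") -> pd.Series:
    """Design-column coefficient means (no ASC) as a labelled Series."""
    _check_group(group)
    return pd.Series({c: _COEF[group][c][0] for c in DESIGN_COLUMNS}, name=group)


def published_standard_errors(group: str = "all") -> pd.Series:
    _check_group(group)
    return pd.Series({c: _COEF[group][c][1] for c in DESIGN_COLUMNS}, name=group)


def published_asc(group: str = "all") -> float:
    _check_group(group)
    return _COEF[group]["asc_opt_out"][0]


def published_n_obs(group: str = "all") -> int:
    """Estimation rows: alternatives x scored tasks x respondents."""
    _check_group(group)
    return N_ALTERNATIVES * SCORED_TASKS * GROUP_SIZES[group]


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise KeyError(f"unknown respondent group {group!r}; expected one of {GROUPS}")


def published_estimation_result(group: str = "all"):
    """The published estimates wrapped as an :class:`EstimationResult`.

    SDs of the random coefficients were not printed and are left empty;
    the wrapper is sufficient for weight/WTP derivation, which uses only
    the coefficient means.
    """
    from .estimation import EstimationResult, information_criteria

    ll = LOG_LIKELIHOOD[group]
    n_obs = published_n_obs(group)
    aic, bic = information_criteria(ll, N_PARAMETERS, n_obs)
    return EstimationResult(
        means=published_means(group),
        mean_se=published_standard_errors(group),
        asc=published_asc(group),
        asc_se=_COEF[group]["asc_opt_out"][1],
        sds=pd.Series(dtype=float),
        sd_se=pd.Series(dtype=float),
        log_likelihood=ll,
        k=N_PARAMETERS,
        n_obs=n_obs,
        aic=aic,
        bic=bic,
        n_draws=0,
        seed=None,
        converged=True,
        model="published mixed logit",
    )
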