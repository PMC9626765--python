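"""Published summary statistics of the underlying field survey.

The survey's raw per-sample data are not deposited, but its published
summary tables give per-crop mean concentrations and the risk indicators
derived from them.  These constants serve two purposes: they parameterize
the desk-scale reproduction (risk indicators recomputed from the published
means with the default exposure constants) and they are the targets the
synthetic generator emulates.
"""

from __future__ import annotations

import pandas as pd

from .io_config import ParameterSet, default_parameters
from .pollution_index import compute_pi, grade_pi
from .risk import risk_from_concentrations

#: published mean grain concentrations, mg/kg dry weight
REFERENCE_MEANS = {
    "rice": {"F": 1.993, "Cd": 0.082},
    "corn": {"F": 2.866, "Cd": 0.043},
    "wheat": {"F": 4.053, "Cd": 0.135},
}

#: sample count behind each published mean
REFERENCE_N = {"rice": 113, "corn": 119, "wheat": 102}

#: published Cd exceedance percentages vs the GB 2762-2017 limits
REFERENCE_EXCEEDANCE_PCT = {"rice": 11.6, "corn": 13.5, "wheat": 45.1}

#: published single-factor pollution indices and grades (Cd)
REFERENCE_PI = {"rice": 0.408, "corn": 0.434, "wheat": 1.352}
REFERENCE_GRADE = {"rice": "excellent", "corn": "excellent",
                   "wheat": "slight_pollution"}

#: published risk indicators, keyed [population][metric][crop]
REFERENCE_RISK = {
    "adult": {
        "thq_F": {"rice": 0.219, "corn": 0.081, "wheat": 0.171},
        "thq_Cd": {"rice": 0.537, "corn": 0.074, "wheat": 0.343},
        "hi": {"rice": 0.756, "corn": 0.154, "wheat": 0.514},
        "r_cd": {"rice": 3.430e-4, "corn": 0.471e-4, "wheat": 2.190e-4},
    },
    "child": {
        "thq_F": {"rice": 0.264, "corn": 0.288, "wheat": 0.271},
        "thq_Cd": {"rice": 0.649, "corn": 0.267, "wheat": 0.543},
        "hi": {"rice": 0.913, "corn": 0.549, "wheat": 0.814},
        "r_cd": {"rice": 4.150e-4, "corn": 1.670e-4, "wheat": 3.470e-4},
    },
}

#: published F-Cd Pearson correlations (regression of F on Cd)
REFERENCE_CORRELATION = {"rice": 0.3473, "corn": -0.3003, "wheat": 0.3825}


def reference_comparison(params: ParameterSet | None = None) -> pd.DataFrame:
    """Recompute all risk indicators and Pi from the published means.

    Returns a long-format table with one row per (crop, population,
    metric): the value computed by this package from the published mean
    concentrations, the published value, and the relative error.  Pi rows
    carry population ``-``.
    """
    if params is None:
        params = default_parameters()
    rows = []
    for crop, means in REFERENCE_MEANS.items():
        si = params.element("Cd").si_for(crop)
        pi = compute_pi(means["Cd"], si)
        rows.append({
            "crop": crop, "population": "-", "metric": "pi",
            "computed": pi, "published": REFERENCE_PI[crop],
            "computed_grade": grade_pi(pi),
            "published_grade": REFERENCE_GRADE[crop],
        })
        for population in ("adult", "child"):
            res = risk_from_concentrations(means, crop, params, population)
            computed = {
                "thq_F": res.thq["F"],
                "thq_Cd": res.thq["Cd"],
                "hi": res.hi,
                "r_cd": res.r_cd,
            }
            for metric, value in computed.items():
                rows.append({
                    "crop": crop, "population": population, "metric": metric,
                    "computed": value,
                    "published": REFERENCE_RISK[population][metric][crop],
                    "computed_grade": res.r_band if metric == "r_cd" else "",
                    "published_grade": "unacceptable" if metric == "r_cd" else "",
                })
    frame = pd.DataFrame(rows)
    frame["rel_err"] = (
        (frame["computed"] - frame["published"]).abs() / frame["published"].abs()
    )
    return frame
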