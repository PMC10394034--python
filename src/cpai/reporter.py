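"""Two-color APA reporter arithmetic.

A bicistronic reporter places RFP upstream of a proximal PAS and GFP
downstream, so red reports total transcriptional output while green
reports the long (distal) isoform only.  Per-cell log2(R/G) therefore
tracks relative proximal-vs-distal PAS usage, and comparing a test
construct to a control lacking the proximal PAS converts it into an
isoform fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ols_r2


def log2_rg(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell log2(red/green) for double-positive cells, with per
    (condition, construct) mean, SD and n.

    Cells with non-positive red or green signal are excluded.
    """
    df = cells[(cells["red"] > 0) & (cells["green"] > 0)].copy()
    df["log2_rg"] = np.log2(df["red"] / df["green"])
    summary = (
        df.groupby(["condition", "construct"])["log2_rg"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
    )
    return df, summary


def isoform_fractions(
    test_mean: float, ctrl_mean: float, orientation: str = "as_printed"
) -> tuple[float, float]:
    """(fraction_long, fraction_short) from mean log2(R/G) of a test
    construct and of the control construct without a proximal PAS.

    ``as_printed`` implements fraction_long = 2^(test - ctrl) verbatim;
    ``inverted`` negates the exponent, which is the orientation consistent
    with a fluorescence model where green scales with the long-isoform
    fraction (higher R/G = more short isoform).
    """
    if orientation == "as_printed":
        f_long = 2.0 ** (test_mean - ctrl_mean)
    elif orientation == "inverted":
        f_long = 2.0 ** (ctrl_mean - test_mean)
    else:
        raise ValueError("orientation must be 'as_printed' or 'inverted'")
    return f_long, 1.0 - f_long


def dose_response(
    means: pd.Series,
    reference_dose: float | None = None,
    log_dose: bool = True,
) -> dict:
    """Dose trend of mean log2(R/G).

    ``means`` maps dose (numeric, in the assay's concentration units) to
    the mean log2(R/G) at that dose.  Reports the change versus the
    reference dose (lowest tested dose by default) and a linear OLS of
    log2(R/G) on log10(dose) (or raw dose with ``log_dose=False``).
    """
    means = means.sort_index()
    doses = means.index.to_numpy(dtype=float)
    if np.any(doses <= 0) and log_dose:
        raise ValueError("doses must be positive for a log10 dose axis")
    ref = float(doses.min()) if reference_dose is None else float(reference_dose)
    if ref not in set(doses):
        raise ValueError(f"reference dose {ref} not among tested doses")
    delta = means - means.loc[ref]
    x = np.log10(doses) if log_dose else doses
    beta, r2 = ols_r2(means.to_numpy(), x[:, None])
    return {
        "delta_vs_reference": delta,
        "reference_dose": ref,
        "slope": float(beta[1]),
        "intercept": float(beta[0]),
        "r2": float(r2),
    }


def inhibition_vs_baseline(
    baseline_short_fraction,
    inhibition,
    degree: int = 2,
) -> dict:
    """Polynomial fit (default degree 2) of the per-construct inhibition
    readout (e.g. Delta log2(R/G) between the highest and lowest dose)
    against the construct's baseline short-isoform fraction."""
    x = np.asarray(baseline_short_fraction, dtype=float)
    yv = np.asarray(inhibition, dtype=float)
    if len(x) <= degree:
        raise ValueError("need more points than the polynomial degree")
    coefs = np.polyfit(x, yv, degree)
    fitted = np.polyval(coefs, x)
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"coefficients": coefs, "fitted": fitted, "r2": float(r2)}
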