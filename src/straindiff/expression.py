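"""qRT-PCR relative quantification with Gaussian error propagation.

The quantification model is the ΔCt method with an assumed amplification
efficiency (default 2.0, perfect doubling): the relative quantity of a
target gene against the single-copy housekeeping reference is
``E^-(Ct_target - Ct_ref)``.  Inter-run comparability is ensured by dividing
every run's quantities by that run's calibrator quantity.  Technical and
biological replicates are arithmetically averaged and technical-replicate
standard deviations are propagated forward by first-order (Gaussian)
propagation through every transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def relative_quantity(ct_target_mean: float, ct_ref_mean: float,
                      efficiency: float = 2.0) -> float:
    """Relative quantity ``efficiency ** -(ct_target - ct_ref)``."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    return efficiency ** (-(ct_target_mean - ct_ref_mean))


def relative_quantity_sd(ct_target_mean: float, ct_ref_mean: float,
                         sd_target: float, sd_ref: float,
                         efficiency: float = 2.0) -> float:
    """First-order sd of the relative quantity from the two Ct sds:
    ``|q| * ln(E) * sqrt(sd_t^2 + sd_r^2)``."""
    q = relative_quantity(ct_target_mean, ct_ref_mean, efficiency)
    return abs(q) * math.log(efficiency) * math.sqrt(sd_target ** 2
                                                     + sd_ref ** 2)


def calibrate_runs(quantities_by_run: dict[str, dict[str, tuple[float, float]]],
                   calibrator: str) -> dict[str, dict[str, tuple[float, float]]]:
    """Divide each run's (quantity, sd) pairs by that run's calibrator
    quantity, so the calibrator maps to 1.0 in every run.

    First-order ratio propagation:
    ``sd(a/c) = (a/c) * sqrt((sd_a/a)^2 + (sd_c/c)^2)``.
    Raises ``KeyError`` naming any run without the calibrator."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for run, samples in quantities_by_run.items():
        if calibrator not in samples:
            raise KeyError(f"run {run!r} has no calibrator sample "
                           f"{calibrator!r}")
        cal_q, cal_sd = samples[calibrator]
        if cal_q <= 0:
            raise ValueError(f"run {run!r}: calibrator quantity must be > 0")
        out[run] = {}
        for name, (q, sd) in samples.items():
            ratio = q / cal_q
            rel = math.sqrt((sd / q) ** 2 + (cal_sd / cal_q) ** 2) if q else 0.0
            out[run][name] = (ratio, abs(ratio) * rel)
    return out


def aggregate_with_error(values, sds) -> tuple[float, float]:
    """Arithmetic mean of k independent values with Gaussian-propagated sd
    ``sqrt(sum sd_i^2) / k``."""
    values = np.asarray(values, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if values.shape != sds.shape:
        raise ValueError(f"{len(values)} values but {len(sds)} sds")
    if values.size == 0:
        raise ValueError("need at least one value per aggregation level")
    k = values.size
    return float(values.mean()), float(np.sqrt((sds ** 2).sum()) / k)


@dataclass
class RelExpr:
    condition: str
    target: str
    quantity: float
    sd: float

    def __post_init__(self) -> None:
        if self.quantity <= 0:
            raise ValueError("relative quantity must be > 0")
        if self.sd < 0:
            raise ValueError("propagated sd must be >= 0")


def read_ct_table(path) -> pd.DataFrame:
    """Ct input CSV: sample, condition, run, target + replicate Ct columns
    (``ct1``, ``ct2``, ...)."""
    df = pd.read_csv(path)
    required = {"sample", "condition", "run", "target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    if not ct_cols:
        raise ValueError(f"{path}: no replicate Ct columns (ct1, ct2, ...)")
    return df


def summarize_expression(ct_df: pd.DataFrame, reference_gene: str = "rpoD",
                         efficiency: float = 2.0,
                         calibrator_sample: str | None = None
                         ) -> list[RelExpr]:
    """Full quantification chain: technical means -> ΔCt quantities against
    the reference gene -> optional inter-run calibration -> biological
    aggregation per (condition, target), with first-order error propagation
    at every step.  Technical sds enter as the sd of the technical mean
    (sd / sqrt(n))."""
    ct_cols = [c for c in ct_df.columns if c.startswith("ct")]

    tech = {}
    for key, sub in ct_df.groupby(["sample", "condition", "run", "target"]):
        vals = sub[ct_cols].to_numpy(float).ravel()
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"no Ct values for {key}")
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        tech[key] = (float(vals.mean()), float(sd / math.sqrt(len(vals))))

    # ΔCt quantities per (sample, condition, run, target != reference)
    by_run: dict[str, dict[tuple, tuple[float, float]]] = {}
    for (sample, condition, run, target), (mean_t, sd_t) in tech.items():
        if target == reference_gene:
            continue
        ref_key = (sample, condition, run, reference_gene)
        if ref_key not in tech:
            raise KeyError(f"no {reference_gene} Cts for sample {sample!r} "
                           f"in run {run!r}")
        mean_r, sd_r = tech[ref_key]
        q = relative_quantity(mean_t, mean_r, efficiency)
        sd = relative_quantity_sd(mean_t, mean_r, sd_t, sd_r, efficiency)
        by_run.setdefault(run, {})[(sample, condition, target)] = (q, sd)

    if calibrator_sample is not None:
        calibrated: dict[str, dict[tuple, tuple[float, float]]] = {}
        for run, samples in by_run.items():
            cal = [(k, v) for k, v in samples.items()
                   if k[0] == calibrator_sample]
            if not cal:
                raise KeyError(f"run {run!r} has no calibrator sample "
                               f"{calibrator_sample!r}")
            flat = {str(k): v for k, v in samples.items()}
            flat_cal = calibrate_runs({run: flat}, str(cal[0][0]))[run]
            calibrated[run] = {k: flat_cal[str(k)] for k in samples}
        by_run = calibrated

    # biological aggregation per condition x target
    grouped: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for run, samples in by_run.items():
        for (sample, condition, target), (q, sd) in samples.items():
            grouped.setdefault((condition, target), []).append((q, sd))

    out = []
    for (condition, target), pairs in sorted(grouped.items()):
        mean, sd = aggregate_with_error([q for q, _ in pairs],
                                        [s for _, s in pairs])
        out.append(RelExpr(condition, target, mean, sd))
    return out


def expression_to_dataframe(results: list[RelExpr]) -> pd.DataFrame:
    return pd.DataFrame([{
        "condition": r.condition, "target": r.target,
        "relative_quantity": r.quantity, "sd": r.sd} for r in results],
        columns=["condition", "target", "relative_quantity", "sd"])
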