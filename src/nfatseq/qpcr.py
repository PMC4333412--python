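"""ChIP-qPCR occupancy quantification.

Immunoprecipitation efficiency is expressed as percent input: the Ct of the
reserved input chromatin is first adjusted for the input fraction (an input
that is 10% of the ChIP chromatin sits log2(10) cycles "ahead" of a full
input at perfect doubling), then

    percent_input = 100 * E ** (adjusted_ct_input - ct_ip)

with amplification efficiency E = 2.0 by default.  Relative occupancy
divides a region's percent input by its plate's control region; fold changes
normalize per-condition occupancy to the untreated baseline.  Technical
replicates are averaged on the Ct scale before transformation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_formats import ValidationError, log

CT_TSV_COLUMNS = ["region", "antibody", "condition", "replicate",
                  "ct_ip", "ct_input", "input_fraction"]


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 1.0,
                  efficiency: float = 2.0) -> float:
    """Immunoprecipitated DNA as a percentage of total input chromatin."""
    if not (0 < input_fraction <= 1):
        raise ValidationError(f"input_fraction must lie in (0, 1], got {input_fraction}")
    if not (0 < ct_ip <= 45 and 0 < ct_input <= 45):
        raise ValidationError("Ct values must lie in (0, 45]")
    adjusted_input = ct_input - math.log(1.0 / input_fraction, efficiency)
    return 100.0 * efficiency ** (adjusted_input - ct_ip)


def relative_occupancy(roi_percent: float, control_percent: float) -> float:
    """Region-of-interest percent input over the control region's."""
    if control_percent == 0:
        log.warning("relative_occupancy: control percent input is 0; returning NA")
        return float("nan")
    return roi_percent / control_percent


def fold_change_vs_baseline(values: dict[str, float], baseline_condition: str
                            ) -> dict[str, float]:
    """Divide each condition's occupancy by the baseline's (baseline -> 1.0)."""
    if baseline_condition not in values:
        raise ValidationError(f"baseline condition {baseline_condition!r} missing")
    base = values[baseline_condition]
    if base <= 0:
        raise ValidationError("baseline occupancy must be > 0")
    return {cond: v / base for cond, v in values.items()}


def quantify_plate(ct_table: pd.DataFrame, control_region: str,
                   baseline_condition: str | None = None,
                   efficiency: float = 2.0) -> pd.DataFrame:
    """Full quantification of one or more plates of Ct measurements.

    ``ct_table`` columns: region, antibody, condition, replicate, ct_ip,
    ct_input, input_fraction, and optionally ``plate`` (each plate is
    normalized to its own control region).  Technical replicates are
    averaged on the Ct scale.  Returns per (plate, antibody, condition,
    region): percent_input, relative_occupancy and, when
    ``baseline_condition`` is given, fold_change_vs_baseline.
    """
    missing = set(CT_TSV_COLUMNS) - set(ct_table.columns)
    if missing:
        raise ValidationError(f"Ct table lacks columns {sorted(missing)}")
    df = ct_table.copy()
    if "plate" not in df.columns:
        df["plate"] = "plate1"

    keys = ["plate", "antibody", "condition", "region"]
    avg = df.groupby(keys, as_index=False).agg(
        ct_ip=("ct_ip", "mean"), ct_input=("ct_input", "mean"),
        input_fraction=("input_fraction", "mean"))
    avg["percent_input"] = [
        percent_input(r.ct_ip, r.ct_input, r.input_fraction, efficiency)
        for r in avg.itertuples()
    ]

    out = []
    for (plate, antibody), sub in avg.groupby(["plate", "antibody"]):
        for cond, csub in sub.groupby("condition"):
            ctrl = csub.loc[csub["region"] == control_region, "percent_input"]
            if ctrl.empty:
                raise ValidationError(
                    f"plate {plate}/{antibody}/{cond}: control region "
                    f"{control_region!r} missing")
            ctrl_pi = float(ctrl.iloc[0])
            csub = csub.assign(relative_occupancy=[
                relative_occupancy(pi, ctrl_pi) for pi in csub["percent_input"]])
            out.append(csub)
    res = pd.concat(out, ignore_index=True)

    if baseline_condition is not None:
        fc = np.full(len(res), np.nan)
        for (plate, antibody, region), sub in res.groupby(["plate", "antibody", "region"]):
            vals = dict(zip(sub["condition"], sub["relative_occupancy"]))
            changes = fold_change_vs_baseline(vals, baseline_condition)
            for i, cond in zip(sub.index, sub["condition"]):
                fc[i] = changes[cond]
        res["fold_change_vs_baseline"] = fc
    return res
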