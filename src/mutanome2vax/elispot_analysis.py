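"""IFN-γ ELISpot response calling.

An antigen is called positive when its mean spot count exceeds the
irrelevant-peptide cutoff (control mean + 2 × sample SD) AND an unpaired
Student t-test against the control wells is significant at alpha. MUT/WT
call pairs are then classified by mutation specificity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONDITIONS = ("MUT", "WT", "positive_control", "irrelevant_control")


@dataclass(frozen=True)
class WellCounts:
    """Spot-forming-cell counts for one antigen/condition across replicate
    wells."""

    antigen: str
    condition: str
    replicates: tuple[float, ...]

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ValueError(f"{self.antigen}/{self.condition}: no replicates")
        if any(r < 0 for r in self.replicates):
            raise ValueError(f"{self.antigen}/{self.condition}: negative SFC")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        if len(self.replicates) < 2:
            logger.warning("%s/%s: single replicate, SD taken as 0",
                           self.antigen, self.condition)
            return 0.0
        return float(np.std(self.replicates, ddof=1))


@dataclass(frozen=True)
class ResponseCall:
    antigen: str
    condition: str
    mean_sfc: float
    cutoff: float
    p_value: float
    positive: bool


def positivity_cutoff(control: WellCounts) -> float:
    """Positivity threshold: control mean plus twice the sample SD."""
    return control.mean + 2.0 * control.sd


def _unpaired_t(test: WellCounts, control: WellCounts) -> float:
    """Two-sided Student (equal-variance) t-test p-value, with the
    degenerate zero-variance case resolved by the means."""
    a = np.asarray(test.replicates, dtype=float)
    b = np.asarray(control.replicates, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        # near-identical replicates trip a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
    return float(p)


def call_response(test: WellCounts, control: WellCounts,
                  alpha: float = 0.05, rule: str = "cutoff+test"
                  ) -> ResponseCall:
    """Call one antigen/condition against the irrelevant-peptide control.

    ``rule`` is ``"cutoff+test"`` (default: both the mean+2SD cutoff and
    p < alpha must hold) or ``"cutoff"`` (threshold only).
    """
    cutoff = positivity_cutoff(control)
    p = _unpaired_t(test, control)
    above = test.mean > cutoff
    positive = above and (rule == "cutoff" or p < alpha)
    return ResponseCall(antigen=test.antigen, condition=test.condition,
                        mean_sfc=test.mean, cutoff=cutoff, p_value=p,
                        positive=positive)


def classify_specificity(mut_call: ResponseCall, wt_call: ResponseCall) -> str:
    """Label the MUT/WT response pattern for one antigen.

    ``MUT_only``: response to the mutant peptide only. ``MUT_and_WT`` /
    ``WT_dominant``: both respond, split by which mean is larger.
    ``negative``: no mutant response.
    """
    if not mut_call.positive:
        return "negative"
    if not wt_call.positive:
        return "MUT_only"
    if wt_call.mean_sfc > mut_call.mean_sfc:
        return "WT_dominant"
    return "MUT_and_WT"


def response_rate(calls: list[ResponseCall]) -> tuple[int, int, int]:
    """(n_positive, n_total, whole percent; half rounds away from zero)."""
    if not calls:
        raise ValueError("no response calls")
    n_pos = sum(c.positive for c in calls)
    pct = int(np.floor(100.0 * n_pos / len(calls) + 0.5))
    return n_pos, len(calls), pct


def read_elispot_csv(path) -> pd.DataFrame:
    """Read an ELISpot plate CSV (antigen, condition, replicate, sfc)."""
    df = pd.read_csv(path)
    required = {"antigen", "condition", "replicate", "sfc"}
    if not required <= set(df.columns):
        raise ValueError(f"ELISpot CSV missing columns: "
                         f"{sorted(required - set(df.columns))}")
    return df


def wells_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], WellCounts]:
    """Group a plate table into WellCounts keyed by (antigen, condition)."""
    wells = {}
    for (antigen, condition), grp in df.groupby(["antigen", "condition"],
                                                sort=True):
        wells[(antigen, condition)] = WellCounts(
            antigen=antigen, condition=condition,
            replicates=tuple(grp["sfc"].astype(float)))
    return wells


def call_plate(df: pd.DataFrame, alpha: float = 0.05,
               rule: str = "cutoff+test") -> pd.DataFrame:
    """Call every MUT/WT antigen condition on a plate against the
    irrelevant control; returns one row per (antigen, condition) with the
    per-antigen specificity label attached to MUT rows."""
    wells = wells_from_frame(df)
    controls = [w for w in wells.values() if w.condition == "irrelevant_control"]
    if not controls:
        raise ValueError("plate has no irrelevant_control wells")
    control = controls[0]
    antigens = sorted({a for a, c in wells if c in ("MUT", "WT")})
    rows = []
    for antigen in antigens:
        calls = {}
        for cond in ("MUT", "WT"):
            if (antigen, cond) in wells:
                calls[cond] = call_response(wells[(antigen, cond)], control,
                                            alpha=alpha, rule=rule)
        spec = None
        if "MUT" in calls:
            wt = calls.get("WT")
            spec = (classify_specificity(calls["MUT"], wt) if wt
                    else ("MUT_only" if calls["MUT"].positive else "negative"))
        for cond, call in calls.items():
            rows.append({"antigen": antigen, "condition": cond,
                         "mean_sfc": call.mean_sfc, "cutoff": call.cutoff,
                         "p_value": call.p_value, "positive": call.positive,
                         "specificity": spec if cond == "MUT" else ""})
    return pd.DataFrame(rows)
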