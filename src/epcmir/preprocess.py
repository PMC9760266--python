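"""Chip QC, presence calling, background subtraction and normalization.

Mirrors the standard preprocessing of serum miRNA oligo-chip data:

1. chip-level QC — a sample is excluded when the coefficient of variation of
   its negative-control spots exceeds 0.15 or it has more than 10 flagged
   (uneven-image) spots; both thresholds are strict inequalities;
2. presence call — a probe is "present" on an array when its raw signal
   exceeds mean + 2·SD of the negative-control signals after trimming the
   top and bottom 5% of spots (floor(0.05·m) per tail, SD with ddof=1);
3. background subtraction — the untrimmed negative-control mean is subtracted
   on the linear scale and the result log2-transformed; probes that are
   absent, flagged, or non-positive after subtraction receive the per-sample
   floor value: lowest detected log2 signal minus 0.1;
4. internal-control normalization — per sample, the mean log2 level of the
   three internal-control miRNAs is shifted to a common target (by default
   the grand mean of the per-sample control means over retained samples),
   removing array-to-array gain offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import INTERNAL_CONTROL_NAMES, ProbeSignalMatrix

__all__ = [
    "QCReport",
    "ExpressionMatrix",
    "qc_filter",
    "presence_threshold",
    "background_subtract_and_call",
    "normalize_internal_controls",
    "preprocess_pipeline",
]


class PreprocessError(ValueError):
    pass


@dataclass
class QCReport:
    """Per-sample chip quality: negative-control CV, flag count, pass flag."""

    table: pd.DataFrame  # columns: neg_control_cv, n_flagged, passed, reasons
    cv_threshold: float = 0.15
    flag_threshold: int = 10

    @property
    def passing_samples(self) -> pd.Index:
        return self.table.index[self.table["passed"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")


@dataclass
class ExpressionMatrix:
    """Log2 expression for target probes after background handling.

    ``values``: target probes x samples (log2); ``present``: boolean presence
    calls; per-sample presence ``thresholds`` and ``neg_means`` (linear
    scale); ``control_values``: log2 levels of the three internal-control
    probes; ``control_present``: their presence calls.
    """

    values: pd.DataFrame
    present: pd.DataFrame
    thresholds: pd.Series
    neg_means: pd.Series
    control_values: pd.DataFrame
    control_present: pd.DataFrame
    normalized: bool = False
    normalization_target: float | None = None

    def validate(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(), present=self.present.copy(),
            thresholds=self.thresholds.copy(), neg_means=self.neg_means.copy(),
            control_values=self.control_values.copy(), control_present=self.control_present.copy(),
            normalized=self.normalized, normalization_target=self.normalization_target,
        )

    def to_tsv(self, path) -> None:
        out = pd.concat([self.values, self.control_values])
        roles = ["target"] * len(self.values.index) + ["internal_control"] * len(self.control_values.index)
        out.insert(0, "probe_role", roles)
        out.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        tab = pd.read_csv(path, sep="\t", index_col="probe_id")
        roles = tab.pop("probe_role")
        values = tab[roles == "target"].astype(float)
        ctrl = tab[roles == "internal_control"].astype(float)
        ones = pd.DataFrame(True, index=values.index, columns=values.columns)
        return cls(
            values=values, present=ones,
            thresholds=pd.Series(np.nan, index=values.columns),
            neg_means=pd.Series(np.nan, index=values.columns),
            control_values=ctrl,
            control_present=pd.DataFrame(True, index=ctrl.index, columns=ctrl.columns),
            normalized=True,
        )


def qc_filter(raw: ProbeSignalMatrix, cv_threshold: float = 0.15, flag_threshold: int = 10) -> QCReport:
    """Chip QC: fail iff negative-control CV > threshold or flags > threshold.

    CV is SD/mean of the raw (linear-scale) negative-control signals; the
    flag count includes every flagged spot on the array.  Both rules are
    strict: CV exactly at the threshold or a flag count exactly at the limit
    passes.
    """
    raw.validate()
    neg = raw.signals.loc[raw.probes_with_role("negative_control")]
    rows = []
    for sample in raw.signals.columns:
        sig = neg[sample].to_numpy(dtype=float)
        mean = sig.mean()
        if mean == 0:
            raise PreprocessError(f"sample {sample}: negative-control mean is zero, CV undefined")
        cv = sig.std(ddof=1) / mean
        n_flagged = int(raw.flags[sample].sum())
        reasons = []
        if cv > cv_threshold:
            reasons.append(f"CV>{cv_threshold:g}")
        if n_flagged > flag_threshold:
            reasons.append(f"flagged>{flag_threshold}")
        rows.append({"sample_id": sample, "neg_control_cv": cv, "n_flagged": n_flagged,
                     "passed": not reasons, "reasons": ";".join(reasons)})
    table = pd.DataFrame(rows).set_index("sample_id")
    return QCReport(table=table, cv_threshold=cv_threshold, flag_threshold=flag_threshold)


def presence_threshold(neg_signals, trim_fraction: float = 0.05, sd_multiplier: float = 2.0) -> float:
    """Detection threshold: trimmed mean + ``sd_multiplier`` x trimmed SD.

    ``floor(trim_fraction * m)`` spots are removed from each extreme of the
    sorted negative-control signals before computing the mean and the
    ddof=1 SD.  Returned on the raw (linear) scale.
    """
    sig = np.sort(np.asarray(neg_signals, dtype=float))
    m = sig.size
    if m < 3:
        raise PreprocessError(f"need at least 3 negative-control spots, got {m}")
    k = int(np.floor(trim_fraction * m))
    trimmed = sig[k:m - k] if k > 0 else sig
    sd = trimmed.std(ddof=1) if trimmed.size > 1 else 0.0
    return float(trimmed.mean() + sd_multiplier * sd)


def background_subtract_and_call(
    raw: ProbeSignalMatrix,
    report: QCReport,
    trim_fraction: float = 0.05,
    sd_multiplier: float = 2.0,
    subtract_trimmed_mean: bool = False,
) -> ExpressionMatrix:
    """Presence calls, background subtraction and floor replacement.

    Only QC-passing samples are processed.  Per sample: probes whose raw
    signal exceeds the presence threshold and that are not flagged are
    "present"; present probes with positive background-subtracted signal get
    ``log2(raw - neg_mean)``; every other probe gets the sample floor
    (minimum detected log2 value - 0.1).  ``subtract_trimmed_mean`` switches
    the background estimate from the untrimmed to the trimmed
    negative-control mean.
    """
    raw.validate()
    samples = [s for s in raw.signals.columns if s in report.passing_samples]
    if not samples:
        raise PreprocessError("no samples passed QC")
    neg_idx = raw.probes_with_role("negative_control")
    target_idx = raw.probes_with_role("target")
    ctrl_idx = pd.Index([p for p in INTERNAL_CONTROL_NAMES if p in raw.signals.index])
    if len(ctrl_idx) != 3:
        ctrl_idx = raw.probes_with_role("internal_control")

    quant_idx = target_idx.append(ctrl_idx)
    value_cols, present_cols = {}, {}
    thresholds, neg_means = {}, {}

    for sample in samples:
        neg = raw.signals.loc[neg_idx, sample].to_numpy(dtype=float)
        thr = presence_threshold(neg, trim_fraction, sd_multiplier)
        if subtract_trimmed_mean:
            srt = np.sort(neg)
            k = int(np.floor(trim_fraction * neg.size))
            bg = float(srt[k:neg.size - k].mean()) if k > 0 else float(neg.mean())
        else:
            bg = float(neg.mean())
        sig = raw.signals.loc[quant_idx, sample].to_numpy(dtype=float)
        flagged = raw.flags.loc[quant_idx, sample].to_numpy(dtype=bool)

        is_present = (sig > thr) & ~flagged
        corrected = sig - bg
        detected = is_present & (corrected > 0)
        if not detected.any():
            raise PreprocessError(f"sample {sample}: no probes detected above background")
        log2_vals = np.full(sig.shape, np.nan)
        log2_vals[detected] = np.log2(corrected[detected])
        floor = np.nanmin(log2_vals) - 0.1
        log2_vals[~detected] = floor

        value_cols[sample] = log2_vals
        present_cols[sample] = is_present
        thresholds[sample] = thr
        neg_means[sample] = bg

    values = pd.DataFrame(value_cols, index=quant_idx)
    present = pd.DataFrame(present_cols, index=quant_idx)
    expr = ExpressionMatrix(
        values=values.loc[target_idx], present=present.loc[target_idx],
        thresholds=pd.Series(thresholds, name="presence_threshold"),
        neg_means=pd.Series(neg_means, name="neg_control_mean"),
        control_values=values.loc[ctrl_idx], control_present=present.loc[ctrl_idx],
    )
    expr.validate()
    return expr


def normalize_internal_controls(expr: ExpressionMatrix, target: float | None = None) -> ExpressionMatrix:
    """Remove per-sample array offsets using the three internal controls.

    Samples in which any internal-control probe failed its presence call are
    excluded with a warning.  Each retained sample is shifted so that its
    3-control log2 mean equals ``target`` (default: the grand mean of the
    per-sample control means over retained samples).  Idempotent.
    """
    ok = expr.control_present.all(axis=0)
    dropped = list(ok.index[~ok])
    if dropped:
        warnings.warn(f"excluding samples with absent internal controls: {dropped}")
    samples = list(ok.index[ok])
    if not samples:
        raise PreprocessError("no samples retain all three internal controls")

    ctrl_means = expr.control_values[samples].mean(axis=0)
    tgt = float(ctrl_means.mean()) if target is None else float(target)
    offsets = ctrl_means - tgt

    out = expr.copy()
    out.values = expr.values[samples].sub(offsets, axis=1)
    out.present = expr.present[samples]
    out.control_values = expr.control_values[samples].sub(offsets, axis=1)
    out.control_present = expr.control_present[samples]
    out.thresholds = expr.thresholds[samples]
    out.neg_means = expr.neg_means[samples]
    out.normalized = True
    out.normalization_target = tgt
    return out


def preprocess_pipeline(
    raw: ProbeSignalMatrix,
    cv_threshold: float = 0.15,
    flag_threshold: int = 10,
    trim_fraction: float = 0.05,
    sd_multiplier: float = 2.0,
    normalization_target: float | None = None,
) -> tuple[QCReport, ExpressionMatrix]:
    """QC -> presence/background -> internal-control normalization."""
    report = qc_filter(raw, cv_threshold, flag_threshold)
    expr = background_subtract_and_call(raw, report, trim_fraction, sd_multiplier)
    return report, normalize_internal_controls(expr, target=normalization_target)
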