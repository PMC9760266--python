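"""Synthetic cohort and serum-miRNA microarray generator.

Emulates the statistical structure of a treatment-naïve advanced-cancer
cohort whose endpoint is palliative-care-unit (PCU) admission within six
months of first visit (the "early deterioration" group, 29/178 of patients
by default), together with raw probe-level fluorescence from a 2,588-probe
serum miRNA oligo chip: target probes, negative-control spots, the three
internal-control miRNAs (miR-149-3p, miR-2861, miR-4463), per-sample array
gain offsets, flagged spots, and a planted differential-expression effect on
a configurable set of informative probes.

Clinical covariates are drawn per outcome group from left-truncated normals
whose truncated mean is moment-matched to the requested group mean (the
truncation floor keeps laboratory values positive); categorical covariates
are drawn from per-group category probabilities.  All randomness flows from
``CohortSpec.seed`` through named sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._stream import substream

__all__ = [
    "ContinuousParam",
    "CategoricalParam",
    "CohortSpec",
    "ProbeSignalMatrix",
    "table2_defaults",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

INTERNAL_CONTROL_NAMES = ("miR-149-3p", "miR-2861", "miR-4463")

#: clinical covariates carried by a cohort table, in column order
CONTINUOUS_VARS = (
    "age", "bmi", "Alb", "AST", "ALT", "ChE", "LDH", "T-Bil", "BUN", "Cre",
    "Na", "K", "Cl", "RBC", "Hb", "Plt", "CRP", "Neut", "Lymp",
)
CATEGORICAL_VARS = ("sex", "primary_site", "stage", "ps")

PRIMARY_SITES = ("Stomach", "Esophagus", "Colorectal", "Biliary tract", "Lung", "Bladder", "Pancreas")


class SpecValidationError(ValueError):
    """A CohortSpec field violates its invariant; the message names the field."""


@dataclass(frozen=True)
class ContinuousParam:
    """Per-group normal parameters for one continuous covariate.

    ``mean0``/``sd0`` describe the non-deterioration group, ``mean1``/``sd1``
    the early-deterioration group.  ``floor`` is the physiologic lower
    truncation bound (> 0 values only are emitted when floor >= 0).
    """

    mean0: float
    sd0: float
    mean1: float
    sd1: float
    floor: float = 0.0


@dataclass(frozen=True)
class CategoricalParam:
    """Per-group category probabilities for one categorical covariate."""

    categories: tuple
    probs0: tuple
    probs1: tuple


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort + chip experiment.

    Defaults (via :func:`table2_defaults`) reproduce the study conditions:
    178 patients, 29 of whom deteriorate early (16.3%), covariate group
    means/SDs and category frequencies from the published cohort table,
    2,565 target probes, and a planted 6-probe log2 effect.
    """

    n_patients: int = 178
    event_fraction: float = 29 / 178
    covariate_params: Mapping[str, object] = field(default_factory=dict)
    n_target_probes: int = 2565
    n_negative_controls: int = 25
    n_internal_controls: int = 3
    informative_probes: tuple = ()  # (probe name, log2 effect in event group)
    flagged_spot_rate: float = 0.001
    seed: int = 0
    # signal-model knobs (log2 scale unless noted)
    probe_baseline_mean: float = 6.5
    probe_baseline_sd: float = 2.0
    probe_noise_sd: float = 0.8  # inter-patient biological + technical, log2
    neg_control_log2_mean: float = 4.0
    neg_control_log2_sd: float = 0.115
    internal_control_log2_level: float = 10.0
    internal_control_noise_sd: float = 0.05
    array_offset_sd: float = 0.3

    def validate(self) -> None:
        if self.n_patients < 2:
            raise SpecValidationError("n_patients must be >= 2")
        if not (0.0 < self.event_fraction < 1.0):
            raise SpecValidationError("event_fraction must lie in (0, 1)")
        if self.n_internal_controls != 3:
            raise SpecValidationError("n_internal_controls must equal 3")
        if self.n_target_probes < 1:
            raise SpecValidationError("n_target_probes must be >= 1")
        if self.n_negative_controls < 3:
            raise SpecValidationError("n_negative_controls must be >= 3")
        if not (0.0 <= self.flagged_spot_rate < 1.0):
            raise SpecValidationError("flagged_spot_rate must lie in [0, 1)")
        for name, par in self.covariate_params.items():
            if isinstance(par, ContinuousParam):
                if par.sd0 <= 0 or par.sd1 <= 0:
                    raise SpecValidationError(f"covariate_params[{name}]: SDs must be > 0")
            elif isinstance(par, CategoricalParam):
                for probs in (par.probs0, par.probs1):
                    if len(probs) != len(par.categories):
                        raise SpecValidationError(f"covariate_params[{name}]: probability length mismatch")
                    if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                        raise SpecValidationError(f"covariate_params[{name}]: probabilities must sum to 1")
            else:
                raise SpecValidationError(f"covariate_params[{name}]: unknown parameter type")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@dataclass
class ProbeSignalMatrix:
    """Raw per-spot fluorescence for one chip batch.

    ``signals``: probes x samples, linear scale; ``roles``: per-probe role in
    {target, negative_control, internal_control}; ``flags``: boolean
    probes x samples uneven-spot marks; ``chip_ids``: per-sample chip id.
    """

    signals: pd.DataFrame
    roles: pd.Series
    flags: pd.DataFrame
    chip_ids: pd.Series

    ROLES = ("target", "negative_control", "internal_control")

    def validate(self) -> None:
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("raw signals must be non-negative")
        if not self.roles.index.equals(self.signals.index):
            raise ValueError("roles index must match signals index")
        if not self.flags.index.equals(self.signals.index) or not self.flags.columns.equals(self.signals.columns):
            raise ValueError("flags must be aligned with signals")
        if (self.roles == "negative_control").sum() < 1:
            raise ValueError("at least one negative-control spot is required")
        n_ic = (self.roles == "internal_control").sum()
        if n_ic != 3:
            raise ValueError(f"expected 3 internal-control probes, found {n_ic}")

    def probes_with_role(self, role: str) -> pd.Index:
        return self.signals.index[self.roles == role]

    # --- plain-text round trip -------------------------------------------
    def to_tsv(self, signals_path, flags_path) -> None:
        out = self.signals.copy()
        out.insert(0, "probe_role", self.roles)
        out.to_csv(signals_path, sep="\t", index_label="probe_id")
        self.flags.astype(int).to_csv(flags_path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, signals_path, flags_path) -> "ProbeSignalMatrix":
        tab = pd.read_csv(signals_path, sep="\t", index_col="probe_id")
        tab.index.name = None
        roles = tab.pop("probe_role")
        flags = pd.read_csv(flags_path, sep="\t", index_col="probe_id").astype(bool)
        flags.index.name = None
        chip_ids = pd.Series({s: s for s in tab.columns}, name="chip_id")
        m = cls(signals=tab.astype(float), roles=roles, flags=flags, chip_ids=chip_ids)
        m.validate()
        return m


def table2_defaults() -> CohortSpec:
    """Study-condition spec: published group means/SDs and category counts.

    Group 0 is the non-deterioration group (n=149), group 1 the early
    deterioration group (n=29).  Laboratory units: Alb g/dL, AST/ALT/LDH U/L,
    ChE U/L, T-Bil mg/dL, BUN/Cre mg/dL, Na/K/Cl mEq/L, RBC 10^4/µL,
    Hb g/dL, Plt 10^4/µL, CRP mg/dL, Neut/Lymp /µL.
    """
    cont = {
        "age": ContinuousParam(64.3, 9.7, 64.3, 9.7, floor=20.0),
        "bmi": ContinuousParam(22.0, 3.0, 22.0, 3.0, floor=10.0),
        "Alb": ContinuousParam(4.2, 0.4, 3.7, 0.6),
        "AST": ContinuousParam(28.3, 36.1, 33.8, 30.8),
        "ALT": ContinuousParam(32.9, 78.9, 27.1, 20.4),
        "ChE": ContinuousParam(255.0, 89.3, 237.4, 105.0),
        "LDH": ContinuousParam(241.7, 171.6, 408.4, 579.9),
        "T-Bil": ContinuousParam(1.00, 2.3, 0.9, 1.0),
        "BUN": ContinuousParam(13.8, 4.4, 14.9, 6.7),
        "Cre": ContinuousParam(0.7, 0.2, 0.8, 0.2),
        "Na": ContinuousParam(139.6, 2.9, 138.5, 5.0, floor=100.0),
        "K": ContinuousParam(4.2, 0.3, 4.2, 0.5, floor=1.5),
        "Cl": ContinuousParam(102.6, 3.3, 102.0, 4.3, floor=70.0),
        "RBC": ContinuousParam(437.7, 48.4, 417.5, 60.3, floor=100.0),
        "Hb": ContinuousParam(13.5, 1.6, 12.5, 1.9, floor=3.0),
        "Plt": ContinuousParam(25.4, 8.7, 24.3, 8.0),
        "CRP": ContinuousParam(1.6, 2.8, 3.7, 5.6),
        "Neut": ContinuousParam(5142.1, 2054.2, 6699.7, 5207.0),
        "Lymp": ContinuousParam(1688.3, 532.1, 1534.5, 617.9),
    }
    cat = {
        "sex": CategoricalParam(("Male", "Female"), (96 / 149, 53 / 149), (20 / 29, 9 / 29)),
        "primary_site": CategoricalParam(
            PRIMARY_SITES,
            (12 / 149, 8 / 149, 6 / 149, 5 / 149, 95 / 149, 0 / 149, 23 / 149),
            (4 / 29, 1 / 29, 1 / 29, 1 / 29, 13 / 29, 1 / 29, 8 / 29),
        ),
        "stage": CategoricalParam((2, 3, 4), (11 / 149, 31 / 149, 107 / 149), (1 / 29, 2 / 29, 26 / 29)),
        "ps": CategoricalParam((0, 1, 2), (83 / 149, 63 / 149, 3 / 149), (11 / 29, 15 / 29, 3 / 29)),
    }
    informative = tuple((f"miR-syn-{i + 1:04d}", 1.0) for i in range(6))
    return CohortSpec(covariate_params={**cont, **cat}, informative_probes=informative)


# --- truncated-normal moment matching -------------------------------------

def _truncated_mean(mu: float, sd: float, floor: float) -> float:
    a = (floor - mu) / sd
    # mean of N(mu, sd) left-truncated at `floor`
    num = math.exp(-0.5 * a * a) / math.sqrt(2 * math.pi)
    den = 0.5 * special.erfc(a / math.sqrt(2))
    if den <= 0:
        return floor
    return mu + sd * num / den

def _match_truncated_location(target_mean: float, sd: float, floor: float) -> float:
    """Location mu such that the floor-truncated N(mu, sd) has the target mean."""
    if target_mean <= floor:
        raise SpecValidationError("continuous covariate mean must exceed its truncation floor")
    lo, hi = target_mean - 40 * sd, target_mean + sd
    return optimize.brentq(lambda m: _truncated_mean(m, sd, floor) - target_mean, lo, hi, xtol=1e-10)

def _draw_truncated(rng: np.random.Generator, n: int, mean: float, sd: float, floor: float) -> np.ndarray:
    mu = _match_truncated_location(mean, sd, floor)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sd, size=max(n - filled, 16))
        keep = draw[draw > floor]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


# --- generation ------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, ProbeSignalMatrix]:
    """Draw one cohort table and its raw probe-signal matrix.

    Deterministic given ``spec.seed``.  The number of early-deterioration
    patients is exactly ``round(event_fraction * n_patients)``; outcome
    labels are randomly interleaved among patient ids.
    """
    spec.validate()
    n = spec.n_patients
    n_event = int(round(spec.event_fraction * n))
    if n_event < 1 or n_event > n - 1:
        raise SpecValidationError("event_fraction yields an empty outcome group")

    rng_assign = substream(spec.seed, "outcome")
    outcome = np.zeros(n, dtype=int)
    outcome[rng_assign.permutation(n)[:n_event]] = 1

    ids = [f"P{i + 1:04d}" for i in range(n)]
    cohort = pd.DataFrame({"patient_id": ids, "early_deterioration": outcome}).set_index("patient_id")

    rng_cov = substream(spec.seed, "covariates")
    for name, par in spec.covariate_params.items():
        if isinstance(par, ContinuousParam):
            vals = np.empty(n)
            for grp, (m, s) in enumerate([(par.mean0, par.sd0), (par.mean1, par.sd1)]):
                mask = outcome == grp
                vals[mask] = _draw_truncated(rng_cov, int(mask.sum()), m, s, par.floor)
            cohort[name] = vals
        else:
            cats = np.asarray(par.categories, dtype=object)
            col = np.empty(n, dtype=object)
            for grp, probs in enumerate([par.probs0, par.probs1]):
                mask = outcome == grp
                col[mask] = rng_cov.choice(cats, size=int(mask.sum()), p=np.asarray(probs, dtype=float))
            cohort[name] = col

    probe_matrix = _generate_signals(spec, outcome, ids)
    return cohort, probe_matrix


def _generate_signals(spec: CohortSpec, outcome: np.ndarray, sample_ids: Sequence[str]) -> ProbeSignalMatrix:
    n = len(sample_ids)
    target_names = [f"miR-syn-{i + 1:04d}" for i in range(spec.n_target_probes)]
    neg_names = [f"NC-{i + 1:03d}" for i in range(spec.n_negative_controls)]
    probe_names = target_names + neg_names + list(INTERNAL_CONTROL_NAMES)
    roles = pd.Series(
        ["target"] * spec.n_target_probes
        + ["negative_control"] * spec.n_negative_controls
        + ["internal_control"] * 3,
        index=probe_names, name="probe_role",
    )

    effects = np.zeros(spec.n_target_probes)
    name_to_idx = {p: i for i, p in enumerate(target_names)}
    for probe, eff in spec.informative_probes:
        if probe not in name_to_idx:
            raise SpecValidationError(f"informative_probes: unknown probe {probe!r}")
        effects[name_to_idx[probe]] = float(eff)

    rng = substream(spec.seed, "signals")
    offsets = rng.normal(0.0, 1.0, size=n) * spec.array_offset_sd  # per-sample log2 array gain
    baselines = rng.normal(spec.probe_baseline_mean, spec.probe_baseline_sd, size=spec.n_target_probes)
    # informative probes model detectable biomarker candidates: their baseline
    # expression is drawn from the upper half of the baseline distribution
    # (below-mean draws reflected upward), keeping them above the detection
    # floor instead of planting effects on probes the chip cannot see
    informative_idx = np.flatnonzero(effects != 0.0)
    baselines[informative_idx] = (
        spec.probe_baseline_mean + np.abs(baselines[informative_idx] - spec.probe_baseline_mean))

    log2_target = (
        baselines[:, None]
        + effects[:, None] * outcome[None, :]
        + offsets[None, :]
        + rng.normal(0.0, spec.probe_noise_sd, size=(spec.n_target_probes, n))
    )
    log2_neg = (
        spec.neg_control_log2_mean
        + offsets[None, :]
        + rng.normal(0.0, spec.neg_control_log2_sd, size=(spec.n_negative_controls, n))
    )
    log2_ic = (
        spec.internal_control_log2_level
        + offsets[None, :]
        + rng.normal(0.0, 1.0, size=(3, n)) * spec.internal_control_noise_sd
    )
    signals = pd.DataFrame(
        np.exp2(np.vstack([log2_target, log2_neg, log2_ic])),
        index=probe_names, columns=list(sample_ids),
    )

    rng_flags = substream(spec.seed, "flags")
    flags = pd.DataFrame(
        rng_flags.random(size=signals.shape) < spec.flagged_spot_rate,
        index=probe_names, columns=list(sample_ids),
    )
    chip_ids = pd.Series({s: f"chip-{s}" for s in sample_ids}, name="chip_id")
    m = ProbeSignalMatrix(signals=signals, roles=roles, flags=flags, chip_ids=chip_ids)
    m.validate()
    return m


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="patient_id")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
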