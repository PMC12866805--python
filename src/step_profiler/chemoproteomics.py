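"""Target calling from a probe-vs-competition TMT reporter-intensity table.

A protein is called a target when the probe group shows a fold change beyond
the gate threshold relative to the competition group and the two-sample test
on log2 intensities is significant. The output table is volcano-ready.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

PROBE = "probe"
COMPETITION = "competition"


@dataclass
class QuantTable:
    """Protein x channel reporter intensities with a channel -> group map.

    Parameters
    ----------
    intensities
        DataFrame indexed by unique protein ids, one column per channel,
        strictly positive finite reporter intensities.
    channel_groups
        Mapping of every channel name to ``"probe"`` or ``"competition"``.
    """

    intensities: pd.DataFrame
    channel_groups: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dupes[:5]}")
        missing = set(self.intensities.columns) - set(self.channel_groups)
        if missing:
            raise ValidationError(f"channels without a group label: {sorted(missing)}")
        bad_groups = {g for g in self.channel_groups.values() if g not in (PROBE, COMPETITION)}
        if bad_groups:
            raise ValidationError(
                f"channel groups must be '{PROBE}' or '{COMPETITION}', got {sorted(bad_groups)}"
            )
        values = self.intensities.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                (str(self.intensities.index[r]), str(self.intensities.columns[c]))
                for r, c in zip(rows[:10], cols[:10])
            ]
            raise ValidationError(f"non-positive or non-finite intensities at cells {cells}")
        for group in (PROBE, COMPETITION):
            if len(self.group_channels(group)) < 2:
                raise ValidationError(f"need >= 2 channels in group '{group}'")

    @property
    def protein_ids(self) -> list[str]:
        return [str(p) for p in self.intensities.index]

    def group_channels(self, group: str) -> list[str]:
        return [c for c in self.intensities.columns if self.channel_groups[c] == group]

    def group_matrix(self, group: str) -> np.ndarray:
        return self.intensities[self.group_channels(group)].to_numpy(dtype=float)


@dataclass
class GateParams:
    """Target-calling gate: |FC| > fc_thresh and p < p_thresh by default."""

    fc_thresh: float = 1.2
    p_thresh: float = 0.05
    use_adjusted_p: bool = False
    two_sided_fc: bool = True

    def __post_init__(self) -> None:
        if not self.fc_thresh > 1:
            raise ConfigError(f"fc_thresh must be > 1, got {self.fc_thresh}")
        if not 0 < self.p_thresh < 1:
            raise ConfigError(f"p_thresh must be in (0, 1), got {self.p_thresh}")


def median_normalize(table: QuantTable) -> QuantTable:
    """Scale each channel so channel medians equal the grand median of the input.

    Idempotent and invariant to per-channel rescaling of the input.
    """
    values = table.intensities.to_numpy(dtype=float)
    channel_medians = np.median(values, axis=0)
    grand_median = np.median(values)
    scaled = values * (grand_median / channel_medians)
    out = pd.DataFrame(scaled, index=table.intensities.index, columns=table.intensities.columns)
    return QuantTable(out, dict(table.channel_groups))


def student_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-tailed.

    Returns ``(t, p)`` with ``df = len(x) + len(y) - 2``. Degenerate
    zero-variance inputs give ``(0, 1)`` when the means agree and ``p = 0``
    with a warning otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("student_t_test requires >= 2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("student_t_test requires finite values")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means; p set to 0", RuntimeWarning, stacklevel=2
        )
        return float(np.inf if diff > 0 else -np.inf), 0.0
    t = diff / np.sqrt(pooled_var * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adjusted
    return out


def call_targets(
    table: QuantTable,
    gate: GateParams | None = None,
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Call targets per protein from a (normalized) QuantTable.

    For each protein: ``log2fc = log2(mean(probe) / mean(competition))`` on
    intensities, a two-sample t-test on log2 intensities, BH adjustment
    across all tested proteins, then the gate. Returns a DataFrame indexed
    by protein id with columns ``log2fc, p_value, p_adj, is_target,
    probe_enriched``, stably sorted by p_value.
    """
    gate = gate or GateParams()
    probe = table.group_matrix(PROBE)
    comp = table.group_matrix(COMPETITION)

    probe_mean = probe.mean(axis=1)
    comp_mean = comp.mean(axis=1)
    # guarded by QuantTable positivity, but zero-mean exclusion is contractual
    usable = comp_mean > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("excluded %d proteins with zero competition-group mean", n_dropped)

    log2fc = np.full(len(table.intensities), np.nan)
    log2fc[usable] = np.log2(probe_mean[usable] / comp_mean[usable])

    lp = np.log2(probe)
    lc = np.log2(comp)
    p_values = np.full(len(table.intensities), np.nan)
    for i in np.nonzero(usable)[0]:
        if welch:
            _, p_values[i] = stats.ttest_ind(lp[i], lc[i], equal_var=False)
        else:
            _, p_values[i] = student_t_test(lp[i], lc[i])

    p_adj = np.full(len(table.intensities), np.nan)
    p_adj[usable] = benjamini_hochberg(p_values[usable])

    gate_p = p_adj if gate.use_adjusted_p else p_values
    log2_thresh = np.log2(gate.fc_thresh)
    if gate.two_sided_fc:
        fc_pass = np.abs(log2fc) > log2_thresh
    else:
        fc_pass = log2fc > log2_thresh
    is_target = usable & fc_pass & (gate_p < gate.p_thresh)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p_values,
            "p_adj": p_adj,
            "is_target": is_target,
            "probe_enriched": log2fc > 0,
        },
        index=table.intensities.index,
    )
    out = out[usable]
    out.index.name = "protein_id"
    return out.sort_values("p_value", kind="mergesort")
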