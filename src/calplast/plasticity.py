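"""Plasticity quantification: intensity dependence, baseline normalization,
weak-responder selection, and probability→rate conversion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from calplast.events import EventStats

__all__ = [
    "CellResponseSummary",
    "DependenceLabel",
    "PlasticityResult",
    "classify_dependence",
    "normalize_to_baseline",
    "rate_from_probability",
    "weak_responder_filter",
]


@dataclass
class CellResponseSummary:
    """Per-cell EventStats keyed by condition.

    For intensity-dependence analysis the keys are 'spontaneous' plus the
    four ascending stimulus intensities; for plasticity analysis they are
    'pre', 'early_post', 'late_post'.
    """

    cell_id: str
    conditions: dict[object, EventStats]
    modality: str = "PF"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("conditions must be non-empty")


@dataclass
class DependenceLabel:
    """Outcome of the stimulus-intensity dependence test for one cell.

    A cell is *dependent* when the Pearson correlation of its response
    measure against condition rank exceeds ``r`` > 0.5 with the correlation
    p-value below the configured cutoff, computed over the five points
    (spontaneous + four intensities).
    """

    r: float
    p: float
    label: str
    degenerate: bool = False


@dataclass
class PlasticityResult:
    """Post-tetanus response measures normalized to the pre-tetanus value."""

    cell_id: str
    norm_amplitude: dict[str, float] = field(default_factory=dict)
    norm_probability: dict[str, float] = field(default_factory=dict)
    pre_amplitude: float = float("nan")
    pre_probability: float = float("nan")


def classify_dependence(
    responses: "CellResponseSummary | np.ndarray | list[float]",
    measure: str = "probability",
    r_threshold: float = 0.5,
    p_cutoff: float = 0.05,
) -> DependenceLabel:
    """Classify a cell as stimulus-intensity dependent or independent.

    The five response values (spontaneous followed by the four ascending
    intensities) are correlated against their condition rank 0..4; the cell
    is labelled ``dependent`` iff Pearson r > ``r_threshold`` and the
    correlation p-value is below ``p_cutoff``.  Rank, not physical
    intensity, is used on the x-axis so that μA and psi designs are
    comparable.

    A degenerate response vector (zero variance) leaves r undefined; such
    cells are labelled independent with ``degenerate=True``.

    Notes
    -----
    The dependence rule is stated with a p cutoff of 0.5 in the original
    protocol; the default here is the conventional 0.05 and the printed 0.5
    remains selectable via ``p_cutoff``.
    """
    if isinstance(responses, CellResponseSummary):
        # spontaneous first, then intensities in ascending order
        keys = sorted(responses.conditions, key=lambda k: (k != "spontaneous", k))
        attr = "probability" if measure == "probability" else "amplitude_mean"
        vals = np.array([getattr(responses.conditions[k], attr) for k in keys])
    else:
        vals = np.asarray(responses, dtype=float)
    if vals.size != 5:
        raise ValueError("dependence test needs exactly five condition points")
    ranks = np.arange(5.0)
    if np.allclose(vals, vals[0]):
        return DependenceLabel(r=float("nan"), p=float("nan"), label="independent", degenerate=True)
    r, p = sps.pearsonr(vals, ranks)
    label = "dependent" if (r > r_threshold and p < p_cutoff) else "independent"
    return DependenceLabel(r=float(r), p=float(p), label=label)


def normalize_to_baseline(
    conditions: dict[str, EventStats], cell_id: str = ""
) -> PlasticityResult:
    """Divide each post-tetanus amplitude and probability by the pre value.

    Requires a 'pre' entry with strictly positive amplitude and probability;
    a cell with no pre-tetanus responses cannot be normalized and raises (it
    belongs in the weak-responder pathway instead).
    """
    if "pre" not in conditions:
        raise ValueError("conditions must include a 'pre' entry")
    pre = conditions["pre"]
    if not np.isfinite(pre.amplitude_mean) or pre.amplitude_mean <= 0:
        raise ValueError(f"cell {cell_id!r}: pre-tetanus amplitude not positive")
    if pre.probability <= 0:
        raise ValueError(f"cell {cell_id!r}: pre-tetanus probability is zero")
    out = PlasticityResult(
        cell_id=cell_id,
        pre_amplitude=pre.amplitude_mean,
        pre_probability=pre.probability,
    )
    for cond, st in conditions.items():
        out.norm_amplitude[cond] = st.amplitude_mean / pre.amplitude_mean
        out.norm_probability[cond] = st.probability / pre.probability
    return out


def rate_from_probability(p: float, window: float = 0.2) -> float:
    """Convert a within-window response probability to an event rate in Hz.

    The linear conversion ``rate = P / window`` maps, with the 200 ms
    window, the spontaneous probability 0.22 to 1.1 Hz and the evoked range
    0.25–0.37 to 1.25–1.85 Hz.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return p / window


def weak_responder_filter(
    cells: dict[str, float],
    inclusion_criterion: float = 0.9,
    factor: float = 2.0,
) -> list[str]:
    """Select cells whose baseline responses stay below the strong-event bound.

    ``cells`` maps cell id to the pre-tetanus mean max-in-window amplitude
    (ΔF/F).  Cells with amplitude strictly below ``factor ×
    inclusion_criterion`` (default 2 × 0.9 = 1.8 ΔF/F, double the calcium
    event inclusion criterion) are retained; the boundary value itself is
    excluded.
    """
    bound = factor * inclusion_criterion
    return [cid for cid, amp in cells.items() if amp < bound]
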