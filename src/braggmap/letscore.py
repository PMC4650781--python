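"""Event-level LET scoring.

Within a thin scoring layer (the 5-µm cell layer), each charged-particle step
contributes an energy deposition ε (keV) over a step length l (µm).  Because
energy deposition is stochastic, ε/l is treated as a random-variable form of
LET.  Two averages are reported:

* track-averaged LET:  LET_t = Σε / Σl  (fluence weighting), and
* dose-averaged LET:   LET_d = Σ ε·(ε/l) / Σ ε  (ε is the dose weight).

By the Cauchy–Schwarz inequality LET_d ≥ LET_t, with equality iff ε/l is
constant across steps.  The probability distribution of ε/l is scored to a
dose-weighted histogram, and the statistical uncertainty of LET_d is
estimated by batch means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, NoSignalError


@dataclass(frozen=True)
class TrackStep:
    """One scoring step: energy deposition ε (keV) over step length l (µm)."""

    energy_deposit: float  # keV
    step_length: float  # um

    def __post_init__(self):
        if self.energy_deposit < 0:
            raise InvalidInputError("energy deposit must be non-negative")
        if self.step_length <= 0:
            raise InvalidInputError("step length must be positive")


@dataclass(frozen=True)
class LetResult:
    let_track: float  # keV/um
    let_dose: float  # keV/um
    stat_uncertainty: float  # relative fraction (of let_dose)
    hist_edges: np.ndarray  # keV/um, log-spaced bin edges
    hist_dose_weight: np.ndarray  # dose weight per bin, sums to 1


def _as_arrays(events) -> tuple[np.ndarray, np.ndarray]:
    eps = np.asarray([e.energy_deposit for e in events], dtype=float)
    length = np.asarray([e.step_length for e in events], dtype=float)
    return eps, length


def score_let(events, n_bins: int = 100) -> LetResult:
    """Score track- and dose-averaged LET of an event stream.

    Zero-ε steps contribute path length to LET_t but carry zero dose weight
    in LET_d and in the histogram.
    """
    if len(events) == 0:
        raise NoSignalError("empty event stream")
    eps, length = _as_arrays(events)
    total_eps = eps.sum()
    if total_eps <= 0:
        raise NoSignalError("event stream deposits no energy")
    ratio = eps / length
    let_track = float(total_eps / length.sum())
    let_dose = float((eps * ratio).sum() / total_eps)

    pos = ratio[eps > 0]
    w = eps[eps > 0]
    lo, hi = pos.min(), pos.max()
    if hi <= lo:  # degenerate spectrum: a narrow band around the single value
        lo, hi = lo * 0.999, hi * 1.001
    with np.errstate(over="ignore"):
        log_spannable = lo > 0 and np.isfinite(hi / lo)
    if log_spannable:
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[0], edges[-1] = lo, hi
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    if not np.all(np.diff(edges) > 0):  # log-spacing underflowed
        edges = np.linspace(lo, hi, n_bins + 1)
    if not np.all(np.diff(edges) > 0):
        edges = np.array([np.nextafter(lo, 0.0), np.nextafter(hi, np.inf)])
    hist, _ = np.histogram(pos, bins=edges, weights=w)
    total = hist.sum()
    hist = (hist / total if total > 0
            else np.full(len(edges) - 1, 1.0 / (len(edges) - 1)))
    return LetResult(
        let_track=let_track,
        let_dose=let_dose,
        stat_uncertainty=let_uncertainty(events) if len(events) >= 20 else 0.0,
        hist_edges=edges,
        hist_dose_weight=hist,
    )


def let_uncertainty(events, batches: int = 10) -> float:
    """Relative statistical uncertainty of LET_d by batch means.

    The stream is split into consecutive batches, LET_d computed per batch,
    and the standard error of the batch means (relative to the overall LET_d)
    returned.  Scales as 1/sqrt(N) for i.i.d. streams.
    """
    if batches < 2:
        raise InvalidInputError("need at least 2 batches")
    if len(events) < 2 * batches:
        raise InsufficientDataError(
            f"need at least {2 * batches} events for {batches} batches")
    eps, length = _as_arrays(events)
    if eps.sum() <= 0:
        raise NoSignalError("event stream deposits no energy")
    ratio = np.where(eps > 0, eps / length, 0.0)
    idx = np.array_split(np.arange(len(events)), batches)
    means = []
    for ix in idx:
        if eps[ix].sum() <= 0:
            continue
        means.append((eps[ix] * ratio[ix]).sum() / eps[ix].sum())
    if len(means) < 2:
        raise InsufficientDataError("too few batches carry dose")
    means = np.asarray(means)
    overall = (eps * ratio).sum() / eps.sum()
    se = means.std(ddof=1) / np.sqrt(len(means))
    return float(se / overall) if overall > 0 else 0.0
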