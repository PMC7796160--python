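"""Absolute qPCR quantification from raw fluorescence curves.

Implements the window-of-linearity approach: after baseline subtraction, the
per-cycle amplification efficiency E is the slope of the best-fitting line of
log10(fluorescence) against cycle over a short window of consecutive cycles
in the exponential phase, and the starting amplicon concentration

    N0 = threshold / E**Cq

where Cq is the fractional cycle at which the corrected fluorescence crosses
the quantification threshold. N0 is expressed in arbitrary fluorescence
units. Two normalization schemes are provided: division by the N0 of an
endogenous reference (relative expression of a target across conditions) and
division by the N0 of the input fraction (ChIP enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, NotComputableError

__all__ = [
    "AmplificationCurve",
    "QuantResult",
    "baseline_correct",
    "fit_efficiency",
    "compute_n0",
    "quantify",
    "relative_expression",
    "chip_enrichment",
    "read_curves_tsv",
    "write_curves_tsv",
]


@dataclass(frozen=True)
class AmplificationCurve:
    """A qPCR fluorescence trajectory for one well."""

    cycles: tuple[int, ...]
    fluorescence: tuple[float, ...]
    well_id: str = ""
    target: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        cycles = tuple(int(c) for c in self.cycles)
        fluor = tuple(float(f) for f in self.fluorescence)
        if len(cycles) != len(fluor):
            raise InvalidParameterError("cycles and fluorescence must have equal length")
        if len(cycles) < 10:
            raise InvalidParameterError("an amplification curve needs at least 10 cycles")
        if not all(math.isfinite(f) for f in fluor):
            raise InvalidParameterError("fluorescence values must be finite")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluor)

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class QuantResult:
    """Derived quantities for one well."""

    well_id: str
    target: str
    sample: str
    baseline: float
    efficiency: float
    window: tuple[int, int]
    r2: float
    threshold: float
    cq: float
    n0: float


def baseline_correct(
    curve: AmplificationCurve, n_baseline_cycles: int = 5
) -> tuple[AmplificationCurve, float]:
    """Subtract the mean fluorescence of the first ``n_baseline_cycles`` cycles.

    ``n_baseline_cycles=0`` is the identity (baseline 0). The chosen count
    must precede the exponential rise for the estimate to be unbiased.
    """
    if n_baseline_cycles < 0 or n_baseline_cycles > len(curve):
        raise InvalidParameterError("n_baseline_cycles out of range")
    if n_baseline_cycles == 0:
        return curve, 0.0
    baseline = float(np.mean(curve.fluorescence[:n_baseline_cycles]))
    corrected = tuple(f - baseline for f in curve.fluorescence)
    return replace(curve, fluorescence=corrected), baseline


def fit_efficiency(
    curve: AmplificationCurve,
    window_len: int = 5,
    min_signal_fraction: float = 0.03,
    max_signal_fraction: float = 0.90,
) -> tuple[float, tuple[int, int], float]:
    """Window-of-linearity efficiency estimate.

    Among windows of ``window_len`` consecutive cycles whose corrected
    fluorescence values are all strictly positive and lie within
    ``[min_signal_fraction, max_signal_fraction]`` of the curve maximum —
    the upper part of the log-linear region, where the signal dominates
    baseline noise and plateau compression has not set in — the window
    maximizing the r^2 of the regression of log10(F) on cycle is selected;
    E = 10**slope. When no window satisfies the signal bounds (short or
    low-amplitude curves) the search falls back to all strictly positive
    windows.

    Returns ``(E, (first_cycle, last_cycle), r2)``. Raises
    :class:`NotComputableError` when no window qualifies or the best window
    implies E <= 1 (non-amplifying well).
    """
    if window_len < 4:
        raise InvalidParameterError("window_len must be >= 4 cycles")
    cycles = np.asarray(curve.cycles, dtype=float)
    fluor = np.asarray(curve.fluorescence, dtype=float)
    fmax = fluor.max()

    def _search(lo: float, hi: float):
        best: Optional[tuple[float, float, tuple[int, int]]] = None  # (r2, slope, window)
        for i in range(len(fluor) - window_len + 1):
            w = fluor[i : i + window_len]
            if np.any(w <= 0) or np.any(w < lo) or np.any(w > hi):
                continue
            res = stats.linregress(cycles[i : i + window_len], np.log10(w))
            r2 = res.rvalue**2
            if math.isnan(r2):
                continue
            if best is None or r2 > best[0]:
                best = (r2, res.slope, (int(cycles[i]), int(cycles[i + window_len - 1])))
        return best

    best = _search(min_signal_fraction * fmax, max_signal_fraction * fmax)
    if best is None:
        best = _search(0.0, math.inf)
    if best is None:
        raise NotComputableError("no window of strictly positive fluorescence; non-amplifying well")
    r2, slope, window = best
    efficiency = 10.0**slope
    if efficiency <= 1.0:
        raise NotComputableError(f"best window implies E={efficiency:.3f} <= 1; non-amplifying well")
    return efficiency, window, r2


def compute_n0(
    curve: AmplificationCurve, efficiency: float, threshold: float
) -> tuple[float, float]:
    """Fractional threshold-crossing cycle Cq and starting concentration N0.

    Cq is found by log-linear interpolation between the last cycle below the
    threshold and the first cycle at/above it; N0 = threshold / E**Cq.
    """
    if efficiency <= 1.0:
        raise InvalidParameterError("efficiency must exceed 1")
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    cycles = np.asarray(curve.cycles, dtype=float)
    fluor = np.asarray(curve.fluorescence, dtype=float)
    if threshold > fluor.max():
        raise NotComputableError("threshold above the curve maximum")
    above = np.flatnonzero(fluor >= threshold)
    i = int(above[0])
    if i == 0 or fluor[i - 1] <= 0:
        raise NotComputableError("threshold below the first positive fluorescence value")
    lo, hi = fluor[i - 1], fluor[i]
    if hi == lo:
        cq = cycles[i]
    else:
        frac = (math.log10(threshold) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
        cq = cycles[i - 1] + frac * (cycles[i] - cycles[i - 1])
    n0 = threshold / efficiency**cq
    return float(cq), float(n0)


def quantify(
    curve: AmplificationCurve,
    n_baseline_cycles: int = 5,
    window_len: int = 5,
    threshold: Optional[float] = None,
    threshold_fraction: float = 0.10,
) -> QuantResult:
    """Full per-well quantification: baseline -> efficiency -> Cq -> N0.

    When no explicit threshold is given it defaults to ``threshold_fraction``
    of the corrected-curve plateau (its maximum), clamped into the
    fluorescence range of the best-fit window so that Cq interpolation happens
    where the exponential model holds.
    """
    corrected, baseline = baseline_correct(curve, n_baseline_cycles)
    efficiency, window, r2 = fit_efficiency(corrected, window_len)
    fluor = np.asarray(corrected.fluorescence, dtype=float)
    if threshold is None:
        threshold = threshold_fraction * float(fluor.max())
        cyc = np.asarray(corrected.cycles)
        in_window = (cyc >= window[0]) & (cyc <= window[1])
        wf = fluor[in_window]
        threshold = float(min(max(threshold, wf.min()), wf.max()))
    cq, n0 = compute_n0(corrected, efficiency, threshold)
    return QuantResult(
        well_id=curve.well_id,
        target=curve.target,
        sample=curve.sample,
        baseline=baseline,
        efficiency=efficiency,
        window=window,
        r2=r2,
        threshold=threshold,
        cq=cq,
        n0=n0,
    )


def _mean_positive(x, what: str) -> float:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 0 or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{what} must be positive and finite")
    return float(arr.mean())


def relative_expression(n0_target, n0_reference, n0_target_control, n0_reference_control) -> float:
    """Reference-normalized fold change of a target vs its control condition.

    Each argument may be a scalar or a sequence of technical replicates;
    replicates are averaged (arithmetic mean of N0) before division:

        fold = (N0_target / N0_reference) / (N0_target_ctl / N0_reference_ctl)
    """
    t = _mean_positive(n0_target, "n0_target")
    r = _mean_positive(n0_reference, "n0_reference")
    tc = _mean_positive(n0_target_control, "n0_target_control")
    rc = _mean_positive(n0_reference_control, "n0_reference_control")
    return (t / r) / (tc / rc)


def chip_enrichment(n0_ip, n0_input) -> float:
    """ChIP signal normalized by the input fraction: N0_IP / N0_input."""
    ip = _mean_positive(n0_ip, "n0_ip")
    inp = _mean_positive(n0_input, "n0_input")
    return ip / inp


# ---------------------------------------------------------------------------
# TSV I/O: long format (well, target, sample, cycle, fluorescence)


def write_curves_tsv(curves: Iterable[AmplificationCurve], path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("well\ttarget\tsample\tcycle\tfluorescence\n")
        for c in curves:
            for cyc, f in zip(c.cycles, c.fluorescence):
                fh.write(f"{c.well_id}\t{c.target}\t{c.sample}\t{cyc}\t{f:.8g}\n")


def read_curves_tsv(path) -> list[AmplificationCurve]:
    df = pd.read_csv(path, sep="\t", comment="#")
    curves = []
    for (well, target, sample), grp in df.groupby(["well", "target", "sample"], sort=True):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                cycles=tuple(grp["cycle"].astype(int)),
                fluorescence=tuple(grp["fluorescence"].astype(float)),
                well_id=str(well),
                target=str(target),
                sample=str(sample),
            )
        )
    return curves
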