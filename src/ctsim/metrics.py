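"""Image-fidelity metrics between simulated and reference volumes.

PSNR, MSE, RMSE and SSIM per matched slice pair, aggregated as
mean ± standard deviation.  Intensities are clipped to an HU window and
mapped to [0, 1] before any metric is computed, so PSNR uses MAX_I = 1
and RMSE magnitudes are on the unit scale; the window used is always
recorded in the report.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import match_positions
from .volume import AxialVolume

__all__ = ["mse", "rmse", "psnr", "ssim", "evaluate", "MetricReport", "DEFAULT_WINDOW"]

#: default HU normalization window: full 12-bit CT range
DEFAULT_WINDOW = (-1024.0, 3071.0)

# standard SSIM reference parameterization
_SSIM_KW = dict(gaussian_weights=True, sigma=1.5, win_size=11, K1=0.01, K2=0.03,
                use_sample_covariance=False)


def mse(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean squared error over all pixels of two equal-shape slices."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return float(np.mean((ref - test) ** 2))


def rmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Root mean squared error: ``sqrt(mse)``."""
    return math.sqrt(mse(ref, test))


def psnr(ref: np.ndarray, test: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``20 log10(max_i / sqrt(MSE))`` in dB.

    Returns ``inf`` for identical slices (MSE = 0).
    """
    if not max_i > 0:
        raise ValueError(f"max_i must be > 0, got {max_i}")
    err = mse(ref, test)
    if err == 0.0:
        return math.inf
    return 20.0 * math.log10(max_i / math.sqrt(err))


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Mean local structural similarity of two slices.

    Both slices are clipped to the HU ``window`` and normalized to [0, 1]
    first; the SSIM itself uses the standard 11x11 Gaussian window with
    sigma 1.5 and stabilizing constants K1 = 0.01, K2 = 0.03, so constant
    (degenerate) pairs are handled without division by zero.
    """
    a = normalize(ref, window)
    b = normalize(test, window)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(structural_similarity(a, b, data_range=1.0, **_SSIM_KW))


def normalize(img: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Clip to the HU window and map it linearly onto [0, 1]."""
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"invalid window {window}: upper bound must exceed lower")
    return (np.clip(np.asarray(img, dtype=np.float64), lo, hi) - lo) / (hi - lo)


@dataclass
class MetricReport:
    """Per-slice-pair and aggregate fidelity metrics.

    ``per_slice`` rows are ``(sim index, ref index, psnr dB, mse, rmse,
    ssim)``; ``aggregate`` maps each metric name to ``(mean, sd)``.
    The normalization window and the MAX_I used for PSNR are recorded so
    the numbers are interpretable.  An optional ``fid`` column is
    reserved for externally computed Fréchet distances.
    """

    per_slice: list[tuple[int, int, float, float, float, float]]
    aggregate: dict[str, tuple[float, float]]
    window: tuple[float, float]
    max_i: float
    unmatched_sim: int = 0
    unmatched_ref: int = 0
    fid: Optional[float] = field(default=None)

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "max_i": self.max_i,
            "unmatched_sim": self.unmatched_sim,
            "unmatched_ref": self.unmatched_ref,
            "aggregate": {k: {"mean": m, "sd": s} for k, (m, s) in self.aggregate.items()},
            "per_slice": [
                {"sim_index": i, "ref_index": j, "psnr": p, "mse": m, "rmse": r, "ssim": s}
                for (i, j, p, m, r, s) in self.per_slice
            ],
            "fid": self.fid,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_json_inf))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sim_index", "ref_index", "psnr_db", "mse", "rmse", "ssim"])
            writer.writerows(self.per_slice)


def _json_inf(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    raise TypeError(f"not JSON serializable: {x!r}")


def evaluate(
    sim: AxialVolume,
    real: AxialVolume,
    tol: float = 0.5,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> MetricReport:
    """Match slices by physical position and score every matched pair.

    Slices are paired with :func:`ctsim.geometry.match_positions` within
    ``tol`` mm; unmatched slices are counted but excluded from the
    aggregates.  Both volumes are windowed and normalized to [0, 1]
    before metrics, so PSNR is reported against MAX_I = 1.

    Raises
    ------
    ValueError
        If the in-plane shapes differ or no slice pair matches.
    """
    if (sim.rows, sim.cols) != (real.rows, real.cols):
        raise ValueError(
            f"in-plane shape mismatch: {(sim.rows, sim.cols)} vs {(real.rows, real.cols)}"
        )
    match = match_positions(sim.positions, real.positions, tol)
    if not match.pairs:
        raise ValueError(f"no slice pairs matched within {tol} mm")

    sim_n = normalize(sim.voxels, window)
    real_n = normalize(real.voxels, window)
    rows = []
    for i, j in match.pairs:
        a, b = real_n[j], sim_n[i]
        m = mse(a, b)
        rows.append((i, j, psnr(a, b, 1.0), m, math.sqrt(m),
                     float(structural_similarity(a, b, data_range=1.0, **_SSIM_KW))))

    aggregate = {}
    for name, col in zip(("psnr", "mse", "rmse", "ssim"), range(2, 6)):
        vals = np.array([r[col] for r in rows], dtype=np.float64)
        with np.errstate(invalid="ignore"):  # infinite PSNR (zero-error pairs)
            aggregate[name] = (float(np.mean(vals)), float(np.std(vals, ddof=0)))
    return MetricReport(
        per_slice=rows,
        aggregate=aggregate,
        window=tuple(window),
        max_i=1.0,
        unmatched_sim=match.unmatched_a,
        unmatched_ref=match.unmatched_b,
    )
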