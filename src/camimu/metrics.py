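"""Per-axis evaluation statistics: RMSE, PRMSE and CMC.

Conventions, applied per axis of the tri-axial acceleration:

* RMSE — root of the mean squared prediction error, m/s².
* PRMSE — RMSE expressed as a percentage of the target's RMS magnitude,
  100 · RMSE / sqrt(mean(G²)).  Normalizing by the RMS (rather than the
  signed mean, which is near zero over a closed reach cycle) keeps the
  percentage well defined and maps "predict zero everywhere" to exactly
  100 %.
* CMC — coefficient of multiple correlation,
  sqrt(max(0, 1 − Σ(G−Ĝ)² / Σ(G−Ḡ)²)), clamped to [0, 1], with the usual
  interpretive bands: ≤ 0.16 poor, (0.16, 0.5) moderate, [0.5, 0.99) good,
  ≥ 0.99 excellent.

A perfect prediction scores RMSE 0, PRMSE 0 % and CMC 1; predicting the
target mean scores CMC 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError

__all__ = [
    "rmse",
    "prmse",
    "cmc",
    "cmc_band",
    "evaluate",
    "EvalReport",
    "AXES",
]

AXES = ("x", "y", "z")


def _aligned(G, G_hat) -> tuple[np.ndarray, np.ndarray]:
    G = np.asarray(G, dtype=float)
    G_hat = np.asarray(G_hat, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G_hat.ndim == 1:
        G_hat = G_hat[:, None]
    if G.shape != G_hat.shape:
        raise AlignmentError(f"series shapes differ: {G.shape} vs {G_hat.shape}")
    if len(G) < 1:
        raise AlignmentError("empty series")
    return G, G_hat


def rmse(G, G_hat) -> np.ndarray:
    """Per-axis root-mean-square error between target and prediction."""
    G, G_hat = _aligned(G, G_hat)
    return np.sqrt(np.mean((G - G_hat) ** 2, axis=0))


def prmse(G, G_hat) -> np.ndarray:
    """Per-axis percent RMSE: 100 · RMSE / RMS(G).

    Raises ``ZeroDivisionError`` for an identically-zero target axis, whose
    percentage error is undefined.
    """
    G, G_hat = _aligned(G, G_hat)
    rms = np.sqrt(np.mean(G**2, axis=0))
    if (rms == 0).any():
        raise ZeroDivisionError("PRMSE undefined: target axis is identically zero")
    return 100.0 * rmse(G, G_hat) / rms


def cmc(G, G_hat) -> np.ndarray:
    """Per-axis coefficient of multiple correlation, clamped to [0, 1].

    Raises ``ZeroDivisionError`` for a constant target axis (the
    denominator Σ(G−Ḡ)² vanishes).
    """
    G, G_hat = _aligned(G, G_hat)
    sse = np.sum((G - G_hat) ** 2, axis=0)
    sst = np.sum((G - G.mean(axis=0)) ** 2, axis=0)
    if (sst == 0).any():
        raise ZeroDivisionError("CMC undefined: target axis is constant")
    return np.sqrt(np.clip(1.0 - sse / sst, 0.0, 1.0))


def cmc_band(value: float) -> str:
    """Interpretive label for a CMC value."""
    if value >= 0.99:
        return "excellent"
    if value >= 0.5:
        return "good"
    if value > 0.16:
        return "moderate"
    return "poor"


@dataclass
class EvalReport:
    """Per-axis metric table for one evaluation, JSON/CSV serializable."""

    rmse: dict[str, float]
    prmse: dict[str, float]
    cmc: dict[str, float]
    cmc_band: dict[str, str]
    n_frames: int
    target_mean: dict[str, float]

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {
                "rmse": self.rmse,
                "prmse": self.prmse,
                "cmc": self.cmc,
                "cmc_band": self.cmc_band,
                "n_frames": self.n_frames,
                "target_mean": self.target_mean,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "EvalReport":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            rmse=d["rmse"],
            prmse=d["prmse"],
            cmc=d["cmc"],
            cmc_band=d["cmc_band"],
            n_frames=d["n_frames"],
            target_mean=d["target_mean"],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "axis": ax,
                "rmse": self.rmse[ax],
                "prmse": self.prmse[ax],
                "cmc": self.cmc[ax],
                "cmc_band": self.cmc_band[ax],
            }
            for ax in AXES
        ]
        return pd.DataFrame(rows)


def evaluate(G, G_hat) -> EvalReport:
    """All three statistics per axis, with CMC band labels."""
    G, G_hat = _aligned(G, G_hat)
    if G.shape[1] != 3:
        raise AlignmentError(f"evaluate expects tri-axial series, got {G.shape}")
    r = rmse(G, G_hat)
    p = prmse(G, G_hat)
    c = cmc(G, G_hat)
    return EvalReport(
        rmse={ax: float(r[i]) for i, ax in enumerate(AXES)},
        prmse={ax: float(p[i]) for i, ax in enumerate(AXES)},
        cmc={ax: float(c[i]) for i, ax in enumerate(AXES)},
        cmc_band={ax: cmc_band(float(c[i])) for i, ax in enumerate(AXES)},
        n_frames=len(G),
        target_mean={ax: float(G[:, i].mean()) for i, ax in enumerate(AXES)},
    )
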