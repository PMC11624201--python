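"""Relative intensity (net water uptake) and its linear / GPR age models.

Relative intensity (RI) is the fractional attenuation deficit of the lesion
against its mirrored contralateral region,

    RI = (mean HU_mirror - mean HU_lesion) / mean HU_mirror,

computed only over voxels inside the 20-80 HU window (bone, CSF and chronic
infarct excluded) on the raw-HU resampled volume — z-scoring is a CNN input
step and would destroy the physical meaning of RI. RI is the established
NCCT proxy for ischemic water uptake and serves as the comparator model
throughout: lesion age (onset-to-scan, OTS) is regressed on RI after a
natural-log transform of OTS, either linearly or with a Gaussian-process
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression

from .io_preprocess import HU_WINDOW, ImageVolume, LesionMask, hu_window_restrict

__all__ = ["RIValue", "AgeEstimate", "relative_intensity", "fit_ri_model", "RIAgeModel"]


@dataclass
class RIValue:
    ri: float
    n_lesion_voxels: int
    n_mirror_voxels: int


@dataclass
class AgeEstimate:
    """Onset-to-scan estimate in hours; kept alongside its natural log."""

    ots_hours: float
    log_ots: float
    model_id: str

    def __post_init__(self) -> None:
        if not np.isclose(self.ots_hours, np.exp(self.log_ots), rtol=1e-9):
            raise ValueError("ots_hours must equal exp(log_ots)")

    @classmethod
    def from_log(cls, log_ots: float, model_id: str) -> "AgeEstimate":
        return cls(float(np.exp(log_ots)), float(log_ots), model_id)


def relative_intensity(
    v: ImageVolume,
    lesion: LesionMask,
    mirror: LesionMask,
    window: tuple[float, float] = HU_WINDOW,
) -> RIValue:
    """RI from raw-HU means over HU-windowed lesion and mirror voxels."""
    lesion_w = hu_window_restrict(v, lesion, *window)
    mirror_w = hu_window_restrict(v, mirror, *window)
    mean_lesion = float(v.data[lesion_w.data].mean())
    mean_mirror = float(v.data[mirror_w.data].mean())
    if mean_mirror <= 0:
        raise ValueError("non-positive mirror attenuation")
    ri = (mean_mirror - mean_lesion) / mean_mirror
    return RIValue(ri, lesion_w.count(), mirror_w.count())


def _default_gpr(seed: int = 0, n_restarts: int = 1) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0) * RBF(length_scale=1.0) \
        + WhiteKernel(noise_level=0.5)
    return GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )


class RIAgeModel:
    """log(OTS) ~ RI, linear or Gaussian-process regression."""

    def __init__(self, kind: str, seed: int = 0):
        if kind not in ("linear", "gpr"):
            raise ValueError("kind must be 'linear' or 'gpr'")
        self.kind = kind
        self._xsd = 1.0
        self._xmu = 0.0
        self._est = (LinearRegression() if kind == "linear"
                     else _default_gpr(seed))

    def fit(self, ri: np.ndarray, ots_hours: np.ndarray) -> "RIAgeModel":
        ri = np.asarray(ri, dtype=float).reshape(-1, 1)
        ots = np.asarray(ots_hours, dtype=float)
        if ri.shape[0] < 10:
            raise ValueError("need at least 10 (RI, OTS) pairs")
        if np.any(ots <= 0):
            raise ValueError("ots must be positive")
        sd = ri.std()
        if sd <= 1e-12 * max(1.0, float(np.abs(ri).max())):
            if self.kind == "linear":
                raise ValueError("degenerate RI: zero variance")
            import warnings
            warnings.warn("zero-variance RI input to GPR", RuntimeWarning)
            sd = 1.0
        self._xmu, self._xsd = float(ri.mean()), float(sd)
        self._est.fit((ri - self._xmu) / self._xsd, np.log(ots))
        return self

    def predict_log(self, ri: np.ndarray) -> np.ndarray:
        ri = np.asarray(ri, dtype=float).reshape(-1, 1)
        return self._est.predict((ri - self._xmu) / self._xsd)

    def predict(self, ri: np.ndarray) -> list[AgeEstimate]:
        model_id = f"ri_{self.kind}"
        return [AgeEstimate.from_log(l, model_id) for l in self.predict_log(ri)]


def fit_ri_model(ri, ots_hours, kind: str = "linear", seed: int = 0) -> RIAgeModel:
    """Fit log(OTS) ~ RI; ``kind`` selects linear regression or GPR."""
    return RIAgeModel(kind, seed=seed).fit(np.asarray(ri), np.asarray(ots_hours))
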