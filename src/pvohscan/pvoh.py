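"""PV[O]H core: linear two-phase forward model, inversion, hematocrit.

The probed volume is modeled as three phases — red blood cells (φr),
plasma/fluid (φp) and static tissue (φs) — that fill it completely::

    φr + φp + φs = 1                     (no voids)

Normalized elastic and inelastic emissions are affine in the two mobile
fractions::

    EE = ϑ1 + ϑ2·φp + ϑ3·φr
    IE = ϑ4 + ϑ5·φp + ϑ6·φr

Because the two equations are linearly independent they invert to::

    φr = a + b·(EE/EE0) + c·(IE/IE0)
    φp = d + e·(EE/EE0) + f·(IE/IE0)

with EE0, IE0 the emissions at the start of probing, so all apparent
fractions are relative to an arbitrary reference state.  Apparent
hematocrit is Hct = 100·φr/(φr + φp) (percent); the shipped reference
anchor is Hct = 28.65 at EE/EE0 = IE/IE0 = 1.  In cord tissue the quantity
reads as *turbidity* of the probed fluid, not literal blood hematocrit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCalibrationError,
    InvalidInputError,
    UndefinedHematocritError,
)

#: apparent hematocrit (%) at the reference emissions, the calibration anchor
HCT_REF_DEFAULT = 28.65
#: baseline mobile (blood/fluid) volume fraction φr0+φp0; only the ratio
#: φr0:φp0 affects Hct.  3–5 % is the perfused-skin calibration context.
PHI_TOTAL_DEFAULT = 0.04

_SCHEMA_VERSION = 1


def baseline_fractions(hct_ref: float = HCT_REF_DEFAULT,
                       phi_total: float = PHI_TOTAL_DEFAULT) -> tuple[float, float]:
    """(φr0, φp0) consistent with a reference hematocrit in percent."""
    if not (0 < hct_ref < 100) or not (0 < phi_total < 1):
        raise InvalidInputError("need 0 < hct_ref < 100 and 0 < phi_total < 1")
    phi_r0 = hct_ref / 100.0 * phi_total
    return phi_r0, phi_total - phi_r0


@dataclass(frozen=True)
class ThetaParams:
    """Coefficients of the normalized forward emission model."""

    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    t6: float

    @property
    def determinant(self) -> float:
        return self.t2 * self.t6 - self.t3 * self.t5

    def __post_init__(self):
        if self.determinant == 0.0:
            raise DegenerateCalibrationError(
                "theta is singular (t2*t6 - t3*t5 == 0): EE and IE are not "
                "linearly independent in (phi_p, phi_r)"
            )


@dataclass(frozen=True)
class VolumeFractions:
    """Apparent phase volume fractions; φs closes the unity constraint."""

    phi_r: float
    phi_p: float
    phi_s: float

    @property
    def out_of_range(self) -> bool:
        """True when the linear inversion extrapolated outside [0, 1].

        Out-of-range fractions are flagged, never clamped, so downstream
        images can display them distinctly.
        """
        return not all(0.0 <= v <= 1.0 for v in (self.phi_r, self.phi_p, self.phi_s))


@dataclass(frozen=True)
class CalibrationParams:
    """Inversion coefficients a–f with their reference state.

    Invariants enforced at construction: ``a+b+c == phi_r0`` and
    ``d+e+f == phi_p0`` (so the reference emissions invert to the baseline
    fractions exactly), and ``hct_ref`` consistent with the baseline ratio.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    ee0: float = 1.0
    ie0: float = 1.0
    phi_r0: float = field(default=None)  # type: ignore[assignment]
    phi_p0: float = field(default=None)  # type: ignore[assignment]
    hct_ref: float = field(default=None)  # type: ignore[assignment]
    diagnostics: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if self.ee0 <= 0 or self.ie0 <= 0:
            raise InvalidInputError("reference emissions must be positive")
        r0 = self.a + self.b + self.c
        p0 = self.d + self.e + self.f
        if self.phi_r0 is None:
            object.__setattr__(self, "phi_r0", r0)
        if self.phi_p0 is None:
            object.__setattr__(self, "phi_p0", p0)
        tol = 1e-9 * max(1.0, abs(r0), abs(p0))
        if abs(r0 - self.phi_r0) > tol or abs(p0 - self.phi_p0) > tol:
            raise InvalidInputError(
                "baseline consistency violated: a+b+c must equal phi_r0 and "
                "d+e+f must equal phi_p0"
            )
        if not (0 < self.phi_r0 < 1 and 0 < self.phi_p0 < 1):
            raise InvalidInputError("baseline fractions must lie in (0, 1)")
        hct0 = 100.0 * self.phi_r0 / (self.phi_r0 + self.phi_p0)
        if self.hct_ref is None:
            object.__setattr__(self, "hct_ref", hct0)
        elif abs(hct0 - self.hct_ref) > 1e-9:
            raise InvalidInputError(
                f"hct_ref {self.hct_ref} inconsistent with baseline fractions ({hct0})"
            )

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": _SCHEMA_VERSION,
            **{k: getattr(self, k) for k in "abcdef"},
            "ee0": self.ee0, "ie0": self.ie0,
            "phi_r0": self.phi_r0, "phi_p0": self.phi_p0,
            "hct_ref": self.hct_ref,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        version = payload.pop("schema_version", None)
        if version != _SCHEMA_VERSION:
            raise InvalidInputError(f"unsupported calibration schema version {version!r}")
        return cls(**payload)


def forward(phi_r: float, phi_p: float, theta: ThetaParams) -> tuple[float, float]:
    """Normalized (EE, IE) emitted by a volume with the given mobile fractions."""
    if phi_r < 0 or phi_p < 0 or phi_r + phi_p > 1:
        raise InvalidInputError("need phi_r, phi_p >= 0 and phi_r + phi_p <= 1")
    ee = theta.t1 + theta.t2 * phi_p + theta.t3 * phi_r
    ie = theta.t4 + theta.t5 * phi_p + theta.t6 * phi_r
    return float(ee), float(ie)


def calib_from_theta(theta: ThetaParams, phi_r0: float, phi_p0: float) -> CalibrationParams:
    """Exact analytic inversion of the forward model around a baseline.

    The reference emissions are EE0, IE0 = forward(φr0, φp0); the a–f are the
    2×2 matrix inverse expressed in the normalized coordinates EE/EE0, IE/IE0,
    so the baseline-consistency invariants hold to round-off.
    """
    if not (0 < phi_r0 < 1 and 0 < phi_p0 < 1 and phi_r0 + phi_p0 < 1):
        raise InvalidInputError("baseline fractions must lie in (0,1) with sum < 1")
    ee0, ie0 = forward(phi_r0, phi_p0, theta)
    if ee0 <= 0 or ie0 <= 0:
        raise DegenerateCalibrationError(
            f"baseline emissions must be positive (got ee0={ee0}, ie0={ie0})"
        )
    det = theta.determinant
    # [phi_p, phi_r]^T = M^-1 [ee - t1, ie - t4]^T  with M = [[t2,t3],[t5,t6]]
    # phi_r = (-t5*(ee-t1) + t2*(ie-t4)) / det ; phi_p = (t6*(ee-t1) - t3*(ie-t4)) / det
    b = -theta.t5 * ee0 / det
    c = theta.t2 * ie0 / det
    a = (theta.t5 * theta.t1 - theta.t2 * theta.t4) / det
    e = theta.t6 * ee0 / det
    f = -theta.t3 * ie0 / det
    d = (-theta.t6 * theta.t1 + theta.t3 * theta.t4) / det
    # re-anchor the intercepts exactly onto the baseline (kills round-off in
    # the invariant a+b+c == phi_r0)
    a = phi_r0 - b - c
    d = phi_p0 - e - f
    return CalibrationParams(a=a, b=b, c=c, d=d, e=e, f=f, ee0=ee0, ie0=ie0)


def invert(ee, ie, calib: CalibrationParams) -> VolumeFractions:
    """Invert measured emissions to apparent volume fractions.

    ``phi_s`` closes the unity constraint exactly; out-of-range values are
    flagged on the result, never clamped.
    """
    if ee < 0 or ie < 0:
        raise InvalidInputError("emissions must be nonnegative")
    x = ee / calib.ee0
    y = ie / calib.ie0
    phi_r = calib.a + calib.b * x + calib.c * y
    phi_p = calib.d + calib.e * x + calib.f * y
    return VolumeFractions(phi_r=float(phi_r), phi_p=float(phi_p),
                           phi_s=float(1.0 - phi_r - phi_p))


def invert_stream(ee, ie, calib: CalibrationParams):
    """Vectorized :func:`invert` for arrays; returns (phi_r, phi_p, phi_s, ok).

    ``ok`` is False where any fraction fell outside [0, 1].
    """
    x = np.asarray(ee, dtype=float) / calib.ee0
    y = np.asarray(ie, dtype=float) / calib.ie0
    phi_r = calib.a + calib.b * x + calib.c * y
    phi_p = calib.d + calib.e * x + calib.f * y
    phi_s = 1.0 - phi_r - phi_p
    ok = np.ones_like(phi_r, dtype=bool)
    for arr in (phi_r, phi_p, phi_s):
        ok &= (arr >= 0.0) & (arr <= 1.0)
    return phi_r, phi_p, phi_s, ok


def hematocrit(vf: VolumeFractions | tuple[float, float]) -> float:
    """Apparent hematocrit 100·φr/(φr+φp) in percent."""
    if isinstance(vf, VolumeFractions):
        phi_r, phi_p = vf.phi_r, vf.phi_p
    else:
        phi_r, phi_p = vf
    total = phi_r + phi_p
    if total <= 0:
        raise UndefinedHematocritError(f"phi_r + phi_p = {total} (must be > 0)")
    return 100.0 * phi_r / total


def hematocrit_arrays(phi_r, phi_p):
    """Vectorized apparent Hct; NaN where φr+φp <= 0 instead of raising."""
    phi_r = np.asarray(phi_r, dtype=float)
    total = phi_r + np.asarray(phi_p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, 100.0 * phi_r / total, np.nan)
    return out


# ---------------------------------------------------------------------------
# empirical calibration from a reference series

def load_calib_series(path: str | Path) -> pd.DataFrame:
    """Read a reference series CSV with columns ee_norm, ie_norm, phi_r, phi_p."""
    df = pd.read_csv(path)
    missing = {"ee_norm", "ie_norm", "phi_r", "phi_p"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"calibration series missing columns {sorted(missing)}")
    return df


def _constrained_ols(X: np.ndarray, y: np.ndarray, total: float) -> np.ndarray:
    """OLS of y on X subject to sum(beta) == total (exact KKT solve)."""
    ncol = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    ones = np.ones(ncol)
    kkt = np.zeros((ncol + 1, ncol + 1))
    kkt[:ncol, :ncol] = XtX
    kkt[:ncol, ncol] = ones
    kkt[ncol, :ncol] = ones
    rhs = np.concatenate([Xty, [total]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCalibrationError("constrained least squares singular") from exc
    return sol[:ncol]


def fit_calibration(series: pd.DataFrame,
                    phi_r0: float | None = None,
                    phi_p0: float | None = None,
                    hct_ref: float | None = None) -> CalibrationParams:
    """Fit a–f by least squares on a reference series of known fractions.

    Each response (φr, φp) is regressed on [1, EE/EE0, IE/IE0]; the
    baseline-consistency constraints ``a+b+c = φr0`` and ``d+e+f = φp0`` are
    imposed exactly via equality-constrained least squares, so the fitted
    calibration keeps the reference anchor while remaining optimal subject to
    it.  Residual diagnostics are attached under ``.diagnostics``.
    """
    if phi_r0 is None or phi_p0 is None:
        phi_r0, phi_p0 = baseline_fractions(
            hct_ref if hct_ref is not None else HCT_REF_DEFAULT)
    elif hct_ref is not None:
        implied = 100.0 * phi_r0 / (phi_r0 + phi_p0)
        if abs(implied - hct_ref) > 1e-9:
            raise InvalidInputError("hct_ref inconsistent with baseline fractions")
    if not isinstance(series, pd.DataFrame):
        series = pd.DataFrame(series, columns=["ee_norm", "ie_norm", "phi_r", "phi_p"])
    n = len(series)
    if n < 3:
        raise DegenerateCalibrationError(f"need >= 3 reference rows, got {n}")
    X = np.column_stack([
        np.ones(n),
        series["ee_norm"].to_numpy(dtype=float),
        series["ie_norm"].to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateCalibrationError("reference series design matrix is rank deficient")
    abc = _constrained_ols(X, series["phi_r"].to_numpy(dtype=float), phi_r0)
    def_ = _constrained_ols(X, series["phi_p"].to_numpy(dtype=float), phi_p0)
    diags = {}
    for name, beta, y in (("phi_r", abc, series["phi_r"]), ("phi_p", def_, series["phi_p"])):
        resid = y.to_numpy(dtype=float) - X @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        diags[name] = {
            "rss": float(resid @ resid),
            "r2": float(1.0 - resid @ resid / tss) if tss > 0 else float("nan"),
            "n": n,
        }
    return CalibrationParams(
        a=abc[0], b=abc[1], c=abc[2], d=def_[0], e=def_[1], f=def_[2],
        ee0=1.0, ie0=1.0, diagnostics=diags,
    )
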