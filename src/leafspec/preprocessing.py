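"""Spectral preprocessing transforms applied before PLSR fitting.

All transforms operate on matrices with samples in rows and bands in
columns.  Two of them learn state from the calibration set — MSC (the
reference spectrum) and OSC (orthogonal weight/loading vectors) — and are
re-applied to test spectra without refitting, so no information leaks from
the test set into the model.  The rest (SNV, area normalisation,
de-trending) are row-local and stateless.

Definitions are the canonical chemometrics ones: SNV centres and unit-scales
each spectrum; MSC regresses each spectrum on the mean calibration spectrum
and inverts the fitted affine map; de-trending subtracts a least-squares
polynomial baseline in wavelength (orders 2-4, fitted on wavelengths
rescaled to [-1, 1] for conditioning); OSC follows Wold's original
algorithm, iteratively removing the dominant-variance score constrained
orthogonal to the response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TransformSpec",
    "snv",
    "area_normalise",
    "detrend",
    "msc_fit",
    "msc_apply",
    "osc_fit",
    "osc_apply",
    "fit_transform_spec",
    "apply_transform",
    "parse_transform_name",
    "TRANSFORM_GRID",
]

#: transform names used in pipeline configs and reports
TRANSFORM_GRID = ("raw", "snv", "msc", "normalise", "dtr-2", "dtr-3", "dtr-4", "osc")

_OSC_TOL = 1e-10
_OSC_MAX_ITER = 500


@dataclass
class TransformSpec:
    """A named transform plus any calibration-fitted state."""

    method: str                               # raw | snv | msc | area_normalise | detrend | osc
    order: int | None = None                  # detrend only
    n_components: int | None = None           # osc only
    msc_reference: np.ndarray | None = None
    osc_weights: np.ndarray | None = None     # (n_components, bands)
    osc_loadings: np.ndarray | None = None    # (n_components, bands)
    osc_x_mean: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {"raw", "snv", "msc", "area_normalise", "detrend", "osc"}
        if self.method not in valid:
            raise ValueError(f"unknown transform method {self.method!r}")
        if self.method == "detrend":
            if self.order not in (2, 3, 4):
                raise ValueError("detrend order must be 2, 3 or 4")
        elif self.order is not None:
            raise ValueError("order is only meaningful for detrend")
        if self.method == "osc":
            if self.n_components is None or self.n_components < 1:
                raise ValueError("osc needs n_components >= 1")
        elif self.n_components is not None:
            raise ValueError("n_components is only meaningful for osc")

    @property
    def is_fitted(self) -> bool:
        if self.method == "msc":
            return self.msc_reference is not None
        if self.method == "osc":
            return self.osc_weights is not None
        return True

    @property
    def name(self) -> str:
        """Short display name as used in reports (e.g. ``DTR-2``)."""
        return {
            "raw": "Raw",
            "snv": "SNV",
            "msc": "MSC",
            "area_normalise": "Normalise",
            "detrend": f"DTR-{self.order}",
            "osc": "OSC",
        }[self.method]

    # -- text serialisation so a fitted pipeline can be reloaded bit-exactly
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [float(v) for v in np.ravel(a)]

        d = {
            "method": self.method,
            "order": self.order,
            "n_components": self.n_components,
            "msc_reference": arr(self.msc_reference),
            "osc_x_mean": arr(self.osc_x_mean),
            "params": self.params,
        }
        for key in ("osc_weights", "osc_loadings"):
            a = getattr(self, key)
            d[key] = None if a is None else [[float(v) for v in row] for row in a]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        def arr(v):
            return None if v is None else np.asarray(v, dtype=float)

        return cls(
            method=d["method"],
            order=d.get("order"),
            n_components=d.get("n_components"),
            msc_reference=arr(d.get("msc_reference")),
            osc_weights=arr(d.get("osc_weights")),
            osc_loadings=arr(d.get("osc_loadings")),
            osc_x_mean=arr(d.get("osc_x_mean")),
            params=d.get("params", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TransformSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample sd 1 (n-1)."""
    X = _as_matrix(X)
    # detect exactly-constant rows by range; sd of identical values can be
    # a few ulp above zero after the mean subtraction
    bad = np.flatnonzero(np.ptp(X, axis=1) == 0)
    if bad.size:
        raise ValueError(f"constant spectrum at row {bad[0]}: SNV undefined")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    return (X - mean) / sd


def area_normalise(X: np.ndarray) -> np.ndarray:
    """Divide each row by the sum of its values so rows sum to 1."""
    X = _as_matrix(X)
    area = X.sum(axis=1, keepdims=True)
    bad = np.flatnonzero(area.ravel() <= 0)
    if bad.size:
        raise ValueError(f"non-positive spectral area at row {bad[0]}")
    return X / area


def detrend(
    X: np.ndarray, order: int, wavelengths: np.ndarray | None = None
) -> np.ndarray:
    """Subtract a least-squares polynomial baseline of the given order.

    The fit is in wavelength, rescaled to [-1, 1]; this is an orthogonal
    projection, so applying it twice equals applying it once.
    """
    if order not in (2, 3, 4):
        raise ValueError("detrend order must be 2, 3 or 4")
    X = _as_matrix(X)
    bands = X.shape[1]
    if bands <= order + 1:
        raise ValueError("not enough bands for the requested polynomial order")
    if wavelengths is None:
        x = np.linspace(-1.0, 1.0, bands)
    else:
        wl = np.asarray(wavelengths, dtype=float)
        x = 2.0 * (wl - wl.min()) / (wl.max() - wl.min()) - 1.0
    V = np.vander(x, order + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return X - (X @ Q) @ Q.T


def msc_fit(X_cal: np.ndarray) -> TransformSpec:
    """Learn the MSC reference (mean calibration spectrum)."""
    X_cal = _as_matrix(X_cal)
    if X_cal.shape[0] < 2:
        raise ValueError("MSC needs at least 2 calibration spectra")
    return TransformSpec(method="msc", msc_reference=X_cal.mean(axis=0))


def msc_apply(spec: TransformSpec, X: np.ndarray) -> np.ndarray:
    """Correct each spectrum against the calibration reference.

    For each row x, least-squares fit x = a + b*ref over bands, then return
    (x - a) / b — the affine family {a + b*ref} maps back to ref exactly.
    """
    if spec.method != "msc" or spec.msc_reference is None:
        raise ValueError("spec is not a fitted MSC transform")
    X = _as_matrix(X)
    ref = spec.msc_reference
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < 1e-10)
    if bad.size:
        raise ValueError(f"spectrum uncorrelated with reference at row {bad[0]}")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def osc_fit(X_cal: np.ndarray, y_cal: np.ndarray, n_components: int = 1) -> TransformSpec:
    """Wold-style orthogonal signal correction.

    Per component: start from the dominant principal-component score of the
    (deflated) calibration matrix, orthogonalise it against the centred
    response, solve for the weight vector reproducing it, and iterate to
    convergence; then remove the rank-one term t p'.  The stored weights and
    loadings re-apply the filter to new spectra without using their y.
    """
    X_cal = _as_matrix(X_cal)
    y = np.asarray(y_cal, dtype=float).ravel()
    n, bands = X_cal.shape
    if y.size != n:
        raise ValueError("y length must match the number of spectra")
    if n_components < 1:
        raise ValueError("osc needs n_components >= 1")
    if n <= n_components + 1:
        raise ValueError("too few samples for the requested OSC components")
    yc = y - y.mean()
    y_norm2 = yc @ yc
    if y_norm2 == 0:
        raise ValueError("constant response: OSC constraint undefined")

    x_mean = X_cal.mean(axis=0)
    Xc = X_cal - x_mean
    max_rank = min(n - 1, bands)
    if n_components > max_rank:
        raise ValueError(
            f"requested {n_components} components exceeds rank (max {max_rank})"
        )

    weights = np.empty((n_components, bands))
    loadings = np.empty((n_components, bands))
    for k in range(n_components):
        # dominant principal score of the deflated matrix
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        if s[0] < 1e-12:
            raise ValueError(f"matrix rank exhausted after {k} OSC components")
        # orthogonalise against the part of y reachable from X's column
        # space: scores t = Xw live there, so only that part constrains
        # them — and the resulting t_orth stays exactly representable as Xw
        Ur = U[:, s > s[0] * 1e-12]
        y_col = Ur @ (Ur.T @ yc)
        y_col_norm2 = y_col @ y_col
        if y_col_norm2 < 1e-24 * y_norm2:
            y_col_norm2 = np.inf  # y invisible to X: constraint is vacuous
        t = U[:, 0] * s[0]
        for _ in range(_OSC_MAX_ITER):
            t_orth = t - y_col * (y_col @ t) / y_col_norm2
            w, *_ = np.linalg.lstsq(Xc, t_orth, rcond=None)
            t_new = Xc @ w
            if np.linalg.norm(t_new - t) <= _OSC_TOL * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        t = t - y_col * (y_col @ t) / y_col_norm2  # enforce the constraint
        tt = t @ t
        if tt < 1e-24:
            raise ValueError(
                f"OSC component {k + 1} degenerate (no y-orthogonal variance)"
            )
        p = Xc.T @ t / tt
        # sign convention: largest-magnitude loading element positive
        j = int(np.argmax(np.abs(p)))
        if p[j] < 0:
            p, w, t = -p, -w, -t
        weights[k] = w
        loadings[k] = p
        Xc = Xc - np.outer(t, p)

    return TransformSpec(
        method="osc",
        n_components=n_components,
        osc_weights=weights,
        osc_loadings=loadings,
        osc_x_mean=x_mean,
    )


def osc_apply(spec: TransformSpec, X: np.ndarray) -> np.ndarray:
    """Remove the fitted orthogonal components from new spectra."""
    if spec.method != "osc" or spec.osc_weights is None:
        raise ValueError("spec is not a fitted OSC transform")
    X = _as_matrix(X)
    Xc = X - spec.osc_x_mean
    for w, p in zip(spec.osc_weights, spec.osc_loadings):
        t = Xc @ w
        Xc = Xc - np.outer(t, p)
    return Xc + spec.osc_x_mean


def parse_transform_name(name: str) -> tuple[str, dict]:
    """Map a grid name like ``dtr-3`` to (method, keyword arguments)."""
    key = name.strip().lower().replace("_", "-").replace("–", "-")
    if key in ("raw", "none"):
        return "raw", {}
    if key == "snv":
        return "snv", {}
    if key == "msc":
        return "msc", {}
    if key in ("normalise", "normalize", "area-normalise", "area"):
        return "area_normalise", {}
    if key.startswith("dtr-"):
        return "detrend", {"order": int(key.split("-", 1)[1])}
    if key == "osc":
        return "osc", {}
    raise ValueError(f"unknown transform name {name!r}")


def fit_transform_spec(
    name: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    osc_components: int = 1,
) -> TransformSpec:
    """Fit (where needed) the named transform on calibration data."""
    method, kw = parse_transform_name(name)
    if method == "msc":
        return msc_fit(X_cal)
    if method == "osc":
        if y_cal is None:
            raise ValueError("osc requires the calibration response")
        return osc_fit(X_cal, y_cal, n_components=osc_components)
    spec = TransformSpec(method=method, order=kw.get("order"))
    if wavelengths is not None:
        spec.params["wavelengths"] = [float(w) for w in np.asarray(wavelengths)]
    return spec


def apply_transform(spec: TransformSpec, X: np.ndarray) -> np.ndarray:
    """Apply a (fitted) transform to a matrix of spectra."""
    if not spec.is_fitted:
        raise ValueError(f"{spec.method} transform has not been fitted")
    if spec.method == "raw":
        return _as_matrix(X).copy()
    if spec.method == "snv":
        return snv(X)
    if spec.method == "area_normalise":
        return area_normalise(X)
    if spec.method == "detrend":
        wl = spec.params.get("wavelengths")
        return detrend(X, spec.order, None if wl is None else np.asarray(wl))
    if spec.method == "msc":
        return msc_apply(spec, X)
    if spec.method == "osc":
        return osc_apply(spec, X)
    raise AssertionError("unreachable")
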