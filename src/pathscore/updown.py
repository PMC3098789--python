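"""Up/down normalization: two-component gamma mixture per probeset.

Microarray intensities for a single probeset across samples are modelled as a
mixture of two gamma distributions,

    f(x) = w * Gamma(x; k_d, theta_d) + (1 - w) * Gamma(x; k_u, theta_u),

where the component with the larger mean (k * theta) is the "up" (highly
expressive) state.  The posterior probability of the up component, p(A),
places every probeset on a common unit scale, so probabilities of different
genes can later be multiplied and compared across samples and experiments.

Fitting is by expectation-maximisation with two deterministic starts
(median split and the optimal one-dimensional 2-means split); the fit with
the higher log-likelihood wins.  Probesets whose intensities carry no usable
two-component structure (zero variance, or one component collapsing) are
flagged degenerate and their samples receive the uninformative posterior 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, psi, zeta

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GammaMixtureFit",
    "UpProbabilityMatrix",
    "fit_gamma_mixture",
    "posterior_up",
    "updown_normalize",
    "read_expression",
    "write_matrix",
    "read_updown",
]

DEGENERATE_PROB = 0.5  # posterior used when no two-state structure is found
_MIN_WEIGHT = 1e-3


@dataclass
class ExpressionMatrix:
    """Probesets x samples matrix of nonnegative, linear-scale intensities."""

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative (linear scale)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probeset_ids, columns=self.sample_ids)


@dataclass
class UpProbabilityMatrix:
    """Posterior up-state probabilities p(A), rows probesets (or genes)."""

    probeset_ids: list[str]
    sample_ids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any((self.probs < 0) | (self.probs > 1)) or not np.all(
            np.isfinite(self.probs)
        ):
            raise ValueError("up-probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.probeset_ids, columns=self.sample_ids)


@dataclass
class GammaMixtureFit:
    weight_down: float
    shape_down: float
    scale_down: float
    shape_up: float
    scale_up: float
    loglik: float
    converged: bool
    n_iter: int
    degenerate: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def mean_down(self) -> float:
        return self.shape_down * self.scale_down

    @property
    def mean_up(self) -> float:
        return self.shape_up * self.scale_up


def _weighted_gamma_mle(x: np.ndarray, logx: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood (shape, scale) for gamma samples under soft weights.

    ``r`` has one row of responsibilities per component; both components are
    solved together.  The shape solves log(k) - psi(k) = log(mean) -
    mean(log) by Newton iteration from the Minka closed-form start (trigamma
    as zeta(2, k)); the scale follows as mean / k.  Zero within-component
    dispersion yields an infinite shape, which callers treat as degenerate.
    """
    r = np.atleast_2d(r)
    wsum = r.sum(axis=1)
    m = (r @ x) / wsum
    mlog = (r @ logx) / wsum
    s = np.log(m) - mlog
    ok = s > 1e-12
    k = np.full_like(m, np.inf)
    sv = np.where(ok, s, 1.0)
    k0 = (3.0 - sv + np.sqrt((sv - 3.0) ** 2 + 24.0 * sv)) / (12.0 * sv)
    for _ in range(30):
        f = np.log(k0) - psi(k0) - sv
        fp = 1.0 / k0 - zeta(2, k0)
        k_new = k0 - f / fp
        k_new = np.where(k_new <= 0, k0 / 2.0, k_new)
        if np.all(np.abs(k_new - k0) < 1e-11 * k0):
            k0 = k_new
            break
        k0 = k_new
    k[ok] = k0[ok]
    theta = np.where(np.isfinite(k), m / k, 0.0)
    return k, theta


def _gamma_logpdf(x, logx, k, theta):
    # inline (k-1) ln x - x/theta - ln Gamma(k) - k ln theta: avoids per-call
    # distribution-object overhead inside the EM loop
    return (k - 1.0) * logx - x / theta - gammaln(k) - k * np.log(theta)


def _mixture_loglik(x, w, kd, td, ku, tu):
    logx = np.log(x)
    ld = _gamma_logpdf(x, logx, kd, td) + np.log(w)
    lu = _gamma_logpdf(x, logx, ku, tu) + np.log1p(-w)
    m = np.maximum(ld, lu)
    return float(np.sum(m + np.log(np.exp(ld - m) + np.exp(lu - m))))


def _kmeans_1d_split(x: np.ndarray) -> np.ndarray:
    """Boolean mask of the high group under the optimal 1-D 2-means split."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best_i, best_ss = 1, np.inf
    for i in range(1, n):
        ss_lo = csq[i - 1] - csum[i - 1] ** 2 / i
        ss_hi = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        ss = ss_lo + ss_hi
        if ss < best_ss - 1e-15:
            best_ss, best_i = ss, i
    mask = np.zeros(n, dtype=bool)
    mask[order[best_i:]] = True
    return mask


def _em_from_responsibilities(
    x: np.ndarray, logx: np.ndarray, r_up: np.ndarray, max_iter: int, tol: float
) -> GammaMixtureFit | None:
    """Run EM from an initial soft assignment; None when a start is unusable."""
    n = len(x)
    trace: list[float] = []
    prev_ll = -np.inf
    params = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        w_up = float(r_up.mean())
        if w_up < _MIN_WEIGHT or w_up > 1 - _MIN_WEIGHT:
            break
        shapes, scales = _weighted_gamma_mle(x, logx, np.vstack([r_up, 1.0 - r_up]))
        (ku, kd), (tu, td) = shapes, scales
        if not (np.isfinite(ku) and np.isfinite(kd)):
            break
        w_down = 1.0 - w_up
        params = (w_down, kd, td, ku, tu)
        # E-step
        ld = _gamma_logpdf(x, logx, kd, td) + np.log(w_down)
        lu = _gamma_logpdf(x, logx, ku, tu) + np.log(w_up)
        m = np.maximum(ld, lu)
        ll = float(np.sum(m + np.log(np.exp(ld - m) + np.exp(lu - m))))
        trace.append(ll)
        r_up = expit(lu - ld)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    if params is None:
        return None
    w_down, kd, td, ku, tu = params
    if kd * td > ku * tu:  # order components by mean: down <= up
        w_down, kd, td, ku, tu = 1.0 - w_down, ku, tu, kd, td
    degenerate = min(w_down, 1.0 - w_down) < _MIN_WEIGHT
    return GammaMixtureFit(
        weight_down=w_down,
        shape_down=kd,
        scale_down=td,
        shape_up=ku,
        scale_up=tu,
        loglik=trace[-1],
        converged=converged,
        n_iter=it,
        degenerate=degenerate,
        loglik_trace=trace,
    )


def _degenerate_fit(x: np.ndarray) -> GammaMixtureFit:
    m = float(np.mean(x))
    return GammaMixtureFit(
        weight_down=0.5,
        shape_down=1.0,
        scale_down=max(m, 1e-12),
        shape_up=1.0,
        scale_up=max(m, 1e-12),
        loglik=np.nan,
        converged=False,
        n_iter=0,
        degenerate=True,
    )


def fit_gamma_mixture(
    values: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_n: int = 8,
) -> GammaMixtureFit:
    """Fit the two-gamma mixture to one probeset's intensities by EM.

    Two deterministic starts are tried — a below/above-median moment split and
    the exact 1-D 2-means split — and the higher-likelihood fit is kept.
    Components are relabelled so that "up" has the larger mean.  Zero-variance
    input yields a degenerate fit (not an error); callers substitute the
    default posterior 0.5 for degenerate probesets.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} values to fit a mixture, got {len(x)}")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("intensities must be finite and nonnegative")
    # gamma support is (0, inf): lift exact zeros by a tiny floor
    floor = np.finfo(float).tiny ** 0.25
    x = np.maximum(x, floor)
    if np.ptp(x) < 1e-12 * max(1.0, float(np.mean(x))):
        return _degenerate_fit(x)
    logx = np.log(x)

    starts = []
    med_mask = x > np.median(x)
    if 0 < med_mask.sum() < len(x):
        starts.append(med_mask)
    km_mask = _kmeans_1d_split(x)
    if 0 < km_mask.sum() < len(x) and not np.array_equal(km_mask, med_mask):
        starts.append(km_mask)

    best: GammaMixtureFit | None = None
    for mask in starts:
        r0 = np.where(mask, 0.99, 0.01)
        fit = _em_from_responsibilities(x, logx, r0, max_iter, tol)
        if fit is not None and (best is None or fit.loglik > best.loglik):
            best = fit
    if best is None:
        return _degenerate_fit(x)
    return best


def posterior_up(values: np.ndarray, fit: GammaMixtureFit) -> np.ndarray:
    """Posterior probability of the up component for each intensity.

    p_i = (1-w) g_u(x_i) / [ w g_d(x_i) + (1-w) g_u(x_i) ], computed in log
    space.  For a degenerate fit every sample receives 0.5.
    """
    x = np.asarray(values, dtype=float)
    floor = np.finfo(float).tiny ** 0.25
    x = np.maximum(x, floor)
    if fit.degenerate:
        return np.full(x.shape, DEGENERATE_PROB)
    logx = np.log(x)
    ld = _gamma_logpdf(x, logx, fit.shape_down, fit.scale_down) + np.log(fit.weight_down)
    lu = _gamma_logpdf(x, logx, fit.shape_up, fit.scale_up) + np.log1p(-fit.weight_down)
    return expit(lu - ld)


def fit_single_gamma_loglik(values: np.ndarray) -> float:
    """Log-likelihood of the one-component gamma MLE (nested-model baseline)."""
    x = np.maximum(np.asarray(values, dtype=float), np.finfo(float).tiny ** 0.25)
    ks, thetas = _weighted_gamma_mle(x, np.log(x), np.ones_like(x))
    k, theta = float(ks[0]), float(thetas[0])
    if not np.isfinite(k):
        return np.inf
    return float(
        np.sum((k - 1) * np.log(x) - x / theta - gammaln(k) - k * np.log(theta))
    )


def _mle_rows(x: np.ndarray, logx: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise weighted gamma MLE: one (shape, scale) per row of ``r``."""
    wsum = r.sum(axis=1)
    m = (r * x).sum(axis=1) / wsum
    mlog = (r * logx).sum(axis=1) / wsum
    s = np.log(m) - mlog
    ok = s > 1e-12
    sv = np.where(ok, s, 1.0)
    k = (3.0 - sv + np.sqrt((sv - 3.0) ** 2 + 24.0 * sv)) / (12.0 * sv)
    for _ in range(30):
        f = np.log(k) - psi(k) - sv
        fp = 1.0 / k - zeta(2, k)
        k_new = k - f / fp
        k_new = np.where(k_new <= 0, k / 2.0, k_new)
        if np.all(np.abs(k_new - k) < 1e-11 * k):
            k = k_new
            break
        k = k_new
    k = np.where(ok, k, np.inf)
    theta = np.where(np.isfinite(k), m / k, 0.0)
    return k, theta


def _batch_em(
    x: np.ndarray, logx: np.ndarray, r0: np.ndarray, max_iter: int, tol: float
) -> dict[str, np.ndarray]:
    """EM for every probeset row at once, from initial responsibilities r0.

    Rows leave the active set when their log-likelihood change falls below
    ``tol`` (relative) or a component collapses; the returned arrays mirror
    the per-vector fit (parameters, loglik, convergence, iteration count,
    validity).  Same update equations as :func:`_em_from_responsibilities`.
    """
    n_rows = x.shape[0]
    out = {
        "weight_down": np.full(n_rows, np.nan),
        "shape_down": np.full(n_rows, np.nan),
        "scale_down": np.full(n_rows, np.nan),
        "shape_up": np.full(n_rows, np.nan),
        "scale_up": np.full(n_rows, np.nan),
        "loglik": np.full(n_rows, -np.inf),
        "converged": np.zeros(n_rows, dtype=bool),
        "n_iter": np.zeros(n_rows, dtype=int),
        "valid": np.zeros(n_rows, dtype=bool),
    }
    prev_ll = np.full(n_rows, -np.inf)
    resp = r0.copy()
    idx = np.arange(n_rows)
    for it in range(1, max_iter + 1):
        xa, la, ra = x[idx], logx[idx], resp[idx]
        w_up = ra.mean(axis=1)
        ku, tu = _mle_rows(xa, la, ra)
        kd, td = _mle_rows(xa, la, 1.0 - ra)
        good = (
            (w_up >= _MIN_WEIGHT)
            & (w_up <= 1 - _MIN_WEIGHT)
            & np.isfinite(ku)
            & np.isfinite(kd)
        )
        gi = idx[good]
        if len(gi) == 0:
            break
        w_down = 1.0 - w_up[good]
        kd_g, td_g, ku_g, tu_g = kd[good], td[good], ku[good], tu[good]
        out["weight_down"][gi] = w_down
        out["shape_down"][gi] = kd_g
        out["scale_down"][gi] = td_g
        out["shape_up"][gi] = ku_g
        out["scale_up"][gi] = tu_g
        out["valid"][gi] = True
        out["n_iter"][gi] = it
        ld = _gamma_logpdf(xa[good], la[good], kd_g[:, None], td_g[:, None]) + np.log(
            w_down
        )[:, None]
        lu = _gamma_logpdf(xa[good], la[good], ku_g[:, None], tu_g[:, None]) + np.log(
            w_up[good]
        )[:, None]
        m = np.maximum(ld, lu)
        ll = (m + np.log(np.exp(ld - m) + np.exp(lu - m))).sum(axis=1)
        out["loglik"][gi] = ll
        resp[gi] = expit(lu - ld)
        done = np.isfinite(prev_ll[gi]) & (
            np.abs(ll - prev_ll[gi]) <= tol * (np.abs(prev_ll[gi]) + 1e-12)
        )
        out["converged"][gi[done]] = True
        prev_ll[gi] = ll
        idx = gi[~done]
        if len(idx) == 0:
            break
    return out


def updown_normalize(
    expr: ExpressionMatrix,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_n: int = 8,
) -> tuple[UpProbabilityMatrix, pd.DataFrame]:
    """Fit a mixture per probeset and return posteriors plus a fit table.

    All probesets are fitted together with a vectorised EM (two deterministic
    starts per probeset, best log-likelihood kept — the batch counterpart of
    :func:`fit_gamma_mixture`).  The output matrix has the shape of the input
    with every entry in [0, 1]; degenerate probesets become constant rows of
    0.5.  The fit table (one row per probeset) records parameters,
    log-likelihood and convergence flags for diagnostics.
    """
    if len(expr.sample_ids) < min_n:
        raise ValueError(
            f"only {len(expr.sample_ids)} samples; at least {min_n} are needed "
            "to fit per-probeset mixtures — add more samples"
        )
    floor = np.finfo(float).tiny ** 0.25
    x = np.maximum(expr.values, floor)
    n_rows, n_cols = x.shape
    nondeg = np.ptp(x, axis=1) >= 1e-12 * np.maximum(1.0, x.mean(axis=1))
    logx = np.log(x)

    med = np.median(x, axis=1, keepdims=True)
    r_med = np.where(x > med, 0.99, 0.01)
    r_km = np.empty_like(r_med)
    for i in range(n_rows):
        r_km[i] = np.where(_kmeans_1d_split(x[i]), 0.99, 0.01)

    fit_a = _batch_em(x, logx, r_med, max_iter, tol)
    fit_b = _batch_em(x, logx, r_km, max_iter, tol)
    use_b = fit_b["valid"] & (~fit_a["valid"] | (fit_b["loglik"] > fit_a["loglik"]))
    chosen = {
        key: np.where(use_b, fit_b[key], fit_a[key])
        for key in fit_a
    }

    # relabel so the "up" component has the larger mean
    mean_d = chosen["shape_down"] * chosen["scale_down"]
    mean_u = chosen["shape_up"] * chosen["scale_up"]
    flip = mean_d > mean_u
    for a, b in (("shape_down", "shape_up"), ("scale_down", "scale_up")):
        chosen[a], chosen[b] = (
            np.where(flip, chosen[b], chosen[a]),
            np.where(flip, chosen[a], chosen[b]),
        )
    chosen["weight_down"] = np.where(
        flip, 1.0 - chosen["weight_down"], chosen["weight_down"]
    )
    degenerate = (
        ~nondeg
        | ~chosen["valid"].astype(bool)
        | (np.minimum(chosen["weight_down"], 1 - chosen["weight_down"]) < _MIN_WEIGHT)
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        ld = _gamma_logpdf(
            x, logx, chosen["shape_down"][:, None], chosen["scale_down"][:, None]
        ) + np.log(chosen["weight_down"])[:, None]
        lu = _gamma_logpdf(
            x, logx, chosen["shape_up"][:, None], chosen["scale_up"][:, None]
        ) + np.log1p(-chosen["weight_down"])[:, None]
        probs = expit(lu - ld)
    probs[degenerate] = DEGENERATE_PROB
    if degenerate.any():
        logger.info(
            "%d/%d probesets degenerate; posteriors set to %.1f",
            int(degenerate.sum()), n_rows, DEGENERATE_PROB,
        )

    fits = pd.DataFrame(
        {
            "weight_down": chosen["weight_down"],
            "shape_down": chosen["shape_down"],
            "scale_down": chosen["scale_down"],
            "shape_up": chosen["shape_up"],
            "scale_up": chosen["scale_up"],
            "loglik": np.where(chosen["valid"].astype(bool), chosen["loglik"], np.nan),
            "converged": chosen["converged"].astype(bool),
            "n_iter": chosen["n_iter"].astype(int),
            "degenerate": degenerate,
        },
        index=pd.Index(expr.probeset_ids, name="probeset_id"),
    )
    up = UpProbabilityMatrix(list(expr.probeset_ids), list(expr.sample_ids), probs)
    return up, fits


# --- text I/O (RMAexpress-style tab-delimited matrices) ---------------------

def read_expression(path: str | Path, unlog2: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first column probeset ids, header samples.

    ``unlog2=True`` exponentiates log2-scale data back to the linear scale
    expected by the gamma mixture.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = df.to_numpy(dtype=float)
    if unlog2:
        values = np.exp2(values)
    return ExpressionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], values
    )


def write_matrix(frame: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")


def read_updown(path: str | Path) -> UpProbabilityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return UpProbabilityMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )
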