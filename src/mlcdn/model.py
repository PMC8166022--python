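"""The multiple-layer cell line-drug response network (ML-CDN) model.

An ML-CDN is a bipartite graph linking a cell line similarity network (CSN)
to a drug similarity network (DSN) through the observed responses Omega.
The response of a pair (C, D) is predicted as a Gaussian-decay-weighted
average of all other observed responses,

    R_hat(C, D) = sum_{(Ci, Dj) in Omega \\ {(C, D)}} w(C, Ci) w(D, Dj) R(Ci, Dj)
                  / sum w(C, Ci) w(D, Dj),

with weights w(C, Ci) = exp(-(1 - rho(C, Ci))^2 / (2 sigma^2)) on the cell
side and the analogous tau-kernel on the drug side.  The two decay
bandwidths (sigma, tau) are the model's only free parameters and are fitted
by exhaustive grid search on the sum of squared leave-target-out errors
J(sigma, tau) over the observed pairs.  A fitted model predicts responses
for tested pairs, for untested pairs, and -- through a pathway-similarity
vector -- for entirely new samples never profiled for drug response.

Usage follows the statsmodels pattern::

    model = MLCDN(response, csn, dsn)
    res = model.fit()          # exhaustive (sigma, tau) grid search
    print(res.summary())
    pred = res.predict()       # leave-target-out R_hat for every pair
    new = res.predict_new(rho_sample)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureMatrix, ResponseMatrix
from .similarity import SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DecayParams",
    "PredictionResult",
    "GridSearchResult",
    "decay_weight",
    "predict_loo",
    "objective",
    "grid_search",
    "similarity_to_training",
    "predict_new",
    "MLCDN",
    "MLCDNResults",
]

_RHO_TOL = 1e-9
_ONE_TOL = 1e-12


@dataclass(frozen=True)
class DecayParams:
    """The pair of Gaussian decay bandwidths: sigma on the cell-line side,
    tau on the drug side; both restricted to [0, 1]."""

    sigma: float
    tau: float

    def __post_init__(self) -> None:
        for name, v in (("sigma", self.sigma), ("tau", self.tau)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PredictionResult:
    """Predicted responses with provenance.

    ``defined_mask`` is False where the weight denominator vanished and the
    global-mean fallback was used (and for entries outside the requested
    target set, which are NaN).
    """

    values: pd.DataFrame
    defined_mask: pd.DataFrame
    params: DecayParams
    csn_label: str
    dsn_label: str
    mode: str
    fallback_value: float


@dataclass
class GridSearchResult:
    """Outcome of the exhaustive (sigma, tau) search: the argmin (ties
    broken by lowest J, then smallest sigma, then smallest tau), its
    objective value, and the full J surface for inspection."""

    best: DecayParams
    j_best: float
    surface: pd.DataFrame  # index = sigma grid, columns = tau grid


def decay_weight(rho, decay: float):
    """Gaussian decay weight w = exp(-(1 - rho)^2 / (2 decay^2)).

    At decay = 0 the limit convention is the indicator of rho = 1 (w = 1
    iff rho = 1, else 0).  Similarities above 1 beyond rounding tolerance
    are rejected; small overshoot is clipped.
    """
    arr = np.asarray(rho, dtype=float)
    if not (0.0 <= decay <= 1.0):
        raise ValueError(f"decay must be in [0, 1], got {decay}")
    if arr.size and float(arr.max()) > 1.0 + _RHO_TOL:
        raise ValueError(f"similarity {float(arr.max())} exceeds 1")
    arr = np.minimum(arr, 1.0)
    if decay == 0.0:
        w = (arr >= 1.0 - _ONE_TOL).astype(float)
    else:
        diff = 1.0 - arr
        w = np.exp(-(diff * diff) / (2.0 * decay * decay))
    if np.ndim(rho) == 0:
        return float(w)
    return w


# ---------------------------------------------------------------------------
# internal kernels (shared verbatim by objective() and grid_search() so the
# accelerated grid agrees with the per-point objective bit-for-bit)


def _loo_sums(Wc: np.ndarray, Wd: np.ndarray, R0: np.ndarray, M: np.ndarray):
    """Leave-target-out numerator and denominator for every pair (i, j).

    The sum over observed pairs (k, l) != (i, j) is decomposed into k != i
    (any l) plus k == i, l != j.  This avoids subtracting the excluded term
    from the full sum, which loses all precision when the target's own
    weight dominates.  For unobserved targets the decomposition equals the
    full sum, since the omitted (i, j) term is zero there.
    """
    dc = np.diag(Wc).copy()
    Wc0 = Wc.copy()
    np.fill_diagonal(Wc0, 0.0)
    Wd0 = Wd.copy()
    np.fill_diagonal(Wd0, 0.0)
    A1, A1m = Wc0 @ R0, Wc0 @ M
    A2, A2m = dc[:, None] * R0, dc[:, None] * M
    WdT = np.ascontiguousarray(Wd.T)
    Wd0T = np.ascontiguousarray(Wd0.T)
    num = A1 @ WdT + A2 @ Wd0T
    den = A1m @ WdT + A2m @ Wd0T
    return num, den


def _finish_predictions(num, den, fallback):
    defined = den > 0.0
    pred = np.full(num.shape, fallback)
    np.divide(num, den, out=pred, where=defined)
    return pred, defined


def _aligned_arrays(response: ResponseMatrix, csn: SimilarityNetwork, dsn: SimilarityNetwork):
    rho_c = csn.aligned_rho(response.cell_ids)
    rho_d = dsn.aligned_rho(response.drug_ids)
    arr = response.values.to_numpy()
    M = np.isfinite(arr).astype(float)
    R0 = np.where(M > 0, arr, 0.0)
    obs = R0[M > 0]
    if obs.size == 0:
        raise ValueError("response matrix has no observed entries")
    fallback = float(obs.mean())
    return rho_c, rho_d, R0, M, fallback


def predict_loo(
    response: ResponseMatrix,
    csn: SimilarityNetwork,
    dsn: SimilarityNetwork,
    params: DecayParams,
    targets=None,
) -> PredictionResult:
    """Leave-target-out prediction R_hat(C, D) for every cell line-drug pair.

    For each target the weighted sum runs over all observed pairs except the
    target itself; same-cell and same-drug pairs are included.  A vanished
    denominator falls back to the global mean of the observed responses,
    flagged False in ``defined_mask``.  ``targets`` (an iterable of
    (cell_id, drug_id)) restricts the output; other entries are NaN.
    """
    rho_c, rho_d, R0, M, fallback = _aligned_arrays(response, csn, dsn)
    Wc = decay_weight(rho_c, params.sigma)
    Wd = decay_weight(rho_d, params.tau)
    num, den = _loo_sums(Wc, Wd, R0, M)
    pred, defined = _finish_predictions(num, den, fallback)
    values = pd.DataFrame(pred, index=response.cell_ids, columns=response.drug_ids)
    mask = pd.DataFrame(defined, index=response.cell_ids, columns=response.drug_ids)
    if targets is not None:
        keep = pd.DataFrame(False, index=values.index, columns=values.columns)
        for c, d in targets:
            keep.loc[c, d] = True
        values = values.where(keep)
        mask = mask & keep
    return PredictionResult(
        values, mask, params, csn.layer_label, dsn.layer_label, "leave_target_out", fallback
    )


def objective(
    response: ResponseMatrix,
    csn: SimilarityNetwork,
    dsn: SimilarityNetwork,
    params: DecayParams,
) -> float:
    """Sum of squared leave-target-out errors over the observed pairs
    (fallback predictions included in the sum)."""
    rho_c, rho_d, R0, M, fallback = _aligned_arrays(response, csn, dsn)
    Wc = decay_weight(rho_c, params.sigma)
    Wd = decay_weight(rho_d, params.tau)
    num, den = _loo_sums(Wc, Wd, R0, M)
    pred, _ = _finish_predictions(num, den, fallback)
    resid = (R0 - pred) * M
    return float((resid * resid).sum())


def grid_search(
    response: ResponseMatrix,
    csn: SimilarityNetwork,
    dsn: SimilarityNetwork,
    grid_step: float = 0.01,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> GridSearchResult:
    """Exhaustive minimization of the squared-error objective over the
    (sigma, tau) grid (default 0 to 1, step 0.01: 101 x 101 points).

    Per-sigma intermediates are cached, but every grid point performs the
    identical floating-point sequence as :func:`objective`, so the surface
    matches a per-point recomputation exactly.  Ties are broken toward the
    smallest sigma, then the smallest tau.
    """
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("bounds must satisfy 0 <= lo < hi <= 1")
    n_steps = int(round((hi - lo) / grid_step))
    grid = np.round(lo + grid_step * np.arange(n_steps + 1), 10)
    rho_c, rho_d, R0, M, fallback = _aligned_arrays(response, csn, dsn)

    # tau-side weight kernels, reused across every sigma row
    Wd_list = []
    for tau in grid:
        Wd = decay_weight(rho_d, float(tau))
        Wd0 = Wd.copy()
        np.fill_diagonal(Wd0, 0.0)
        Wd_list.append((np.ascontiguousarray(Wd.T), np.ascontiguousarray(Wd0.T)))

    J = np.empty((grid.size, grid.size))
    for a, sigma in enumerate(grid):
        Wc = decay_weight(rho_c, float(sigma))
        dc = np.diag(Wc).copy()
        Wc0 = Wc.copy()
        np.fill_diagonal(Wc0, 0.0)
        A1, A1m = Wc0 @ R0, Wc0 @ M
        A2, A2m = dc[:, None] * R0, dc[:, None] * M
        for b, (WdT, Wd0T) in enumerate(Wd_list):
            num = A1 @ WdT + A2 @ Wd0T
            den = A1m @ WdT + A2m @ Wd0T
            pred, _ = _finish_predictions(num, den, fallback)
            resid = (R0 - pred) * M
            J[a, b] = (resid * resid).sum()

    flat = int(np.argmin(J))  # first minimum in row-major order:
    a, b = divmod(flat, grid.size)  # smallest sigma, then smallest tau
    best = DecayParams(float(grid[a]), float(grid[b]))
    surface = pd.DataFrame(J, index=grid, columns=grid)
    surface.index.name = "sigma"
    surface.columns.name = "tau"
    return GridSearchResult(best, float(J[a, b]), surface)


def similarity_to_training(sample_profile, csn_basis: FeatureMatrix) -> pd.Series:
    """Pearson correlation of a new sample's pathway-activity profile with
    each training cell line's profile.

    ``sample_profile`` is a pandas Series indexed by pathway features (must
    match the basis feature space exactly) or a plain vector in basis
    feature order.
    """
    basis = csn_basis.values
    if isinstance(sample_profile, pd.Series):
        missing = set(basis.columns) - set(sample_profile.index)
        extra = set(sample_profile.index) - set(basis.columns)
        if missing or extra:
            raise ValueError(
                f"feature mismatch with training basis: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        x = sample_profile.reindex(basis.columns).to_numpy(dtype=float)
    else:
        x = np.asarray(sample_profile, dtype=float)
        if x.shape != (basis.shape[1],):
            raise ValueError(
                f"profile length {x.shape} does not match {basis.shape[1]} basis features"
            )
    if not np.isfinite(x).all():
        raise ValueError("sample profile contains non-finite values")
    xc = x - x.mean()
    xnorm = np.sqrt((xc * xc).sum())
    if xnorm == 0:
        raise ValueError("sample profile has zero variance")
    B = basis.to_numpy(dtype=float)
    Bc = B - B.mean(axis=1, keepdims=True)
    bnorm = np.sqrt((Bc * Bc).sum(axis=1))
    if (bnorm == 0).any():
        bad = basis.index[int(np.argmax(bnorm == 0))]
        raise ValueError(f"training profile {bad!r} has zero variance")
    rho = (Bc @ xc) / (bnorm * xnorm)
    return pd.Series(np.clip(rho, -1.0, 1.0), index=basis.index)


def predict_new(
    rho_sample,
    response: ResponseMatrix,
    dsn: SimilarityNetwork,
    params: DecayParams,
    drugs=None,
    sample_id: str = "sample",
) -> PredictionResult:
    """Predict the response of a new sample S to the known drugs.

    S is not part of Omega, so the weighted sum runs over ALL observed
    pairs with no exclusion.  ``rho_sample`` holds rho(S, Ci) for every
    training cell line (a Series indexed by cell id, or a vector in
    response cell order).
    """
    if isinstance(rho_sample, pd.Series):
        missing = [c for c in response.cell_ids if c not in rho_sample.index]
        if missing:
            raise ValueError(f"rho_sample missing cell lines: {missing}")
        rho_vec = rho_sample.reindex(response.cell_ids).to_numpy(dtype=float)
    else:
        rho_vec = np.asarray(rho_sample, dtype=float)
        if rho_vec.shape != (len(response.cell_ids),):
            raise ValueError(
                f"rho_sample length {rho_vec.shape} does not match "
                f"{len(response.cell_ids)} response cell lines"
            )
    arr = response.values.to_numpy()
    M = np.isfinite(arr).astype(float)
    R0 = np.where(M > 0, arr, 0.0)
    obs = R0[M > 0]
    if obs.size == 0:
        raise ValueError("response matrix has no observed entries")
    fallback = float(obs.mean())

    drug_ids = list(response.drug_ids) if drugs is None else list(drugs)
    unknown = [d for d in drug_ids if d not in response.drug_ids]
    if unknown:
        raise ValueError(f"drugs not in the response matrix: {unknown}")
    rho_d = dsn.aligned_rho(response.drug_ids)
    Wd = decay_weight(rho_d, params.tau)
    ws = decay_weight(rho_vec, params.sigma)

    num_all = (ws @ R0) @ Wd.T
    den_all = (ws @ M) @ Wd.T
    sel = [response.drug_ids.index(d) for d in drug_ids]
    pred, defined = _finish_predictions(num_all[sel], den_all[sel], fallback)
    values = pd.DataFrame([pred], index=[sample_id], columns=drug_ids)
    mask = pd.DataFrame([defined], index=[sample_id], columns=drug_ids)
    return PredictionResult(values, mask, params, "sample", dsn.layer_label, "new_sample", fallback)


# ---------------------------------------------------------------------------
# statsmodels-style front end


class MLCDN:
    """Multiple-layer cell line-drug response network model.

    Parameters
    ----------
    response : ResponseMatrix
        Normalized cell line x drug responses (missing entries allowed).
    csn, dsn : SimilarityNetwork
        Cell line and drug similarity networks covering the response ids
        (single-layer or SNF-fused).
    """

    def __init__(self, response: ResponseMatrix, csn: SimilarityNetwork, dsn: SimilarityNetwork):
        # fail fast on id mismatch
        csn.aligned_rho(response.cell_ids)
        dsn.aligned_rho(response.drug_ids)
        if response.n_observed == 0:
            raise ValueError("response matrix has no observed entries")
        self.response = response
        self.csn = csn
        self.dsn = dsn

    @classmethod
    def from_dataframes(
        cls,
        response: pd.DataFrame,
        csn: pd.DataFrame,
        dsn: pd.DataFrame,
        csn_label: str = "csn",
        dsn_label: str = "dsn",
        csn_measure: str = "pearson",
        dsn_measure: str = "snf",
        normalize: bool = False,
    ) -> "MLCDN":
        """Build the model from plain square/rectangular DataFrames."""
        from .io import normalize_ic50

        resp = ResponseMatrix(response)
        if normalize:
            resp = normalize_ic50(resp)
        csn_net = SimilarityNetwork(list(csn.index), csn.to_numpy(), csn_label, csn_measure)
        dsn_net = SimilarityNetwork(list(dsn.index), dsn.to_numpy(), dsn_label, dsn_measure)
        return cls(resp, csn_net, dsn_net)

    def fit(
        self, grid_step: float = 0.01, bounds: tuple[float, float] = (0.0, 1.0)
    ) -> "MLCDNResults":
        """Fit (sigma, tau) by exhaustive grid search and return results."""
        gs = grid_search(self.response, self.csn, self.dsn, grid_step=grid_step, bounds=bounds)
        return MLCDNResults(self, gs)

    def loglike(self):  # pragma: no cover - statsmodels-API politeness
        raise NotImplementedError("ML-CDN is fitted by squared-error grid search, not likelihood")


class MLCDNResults:
    """Results of an ML-CDN fit: the optimized decay parameters, the full
    objective surface, and in-sample leave-target-out diagnostics."""

    def __init__(self, model: MLCDN, grid_result: GridSearchResult):
        self.model = model
        self.grid_result = grid_result
        self.params = grid_result.best
        self.j_best = grid_result.j_best
        self.j_surface = grid_result.surface
        self._insample = predict_loo(model.response, model.csn, model.dsn, self.params)
        mask = model.response.observed_mask.to_numpy()
        obs = model.response.values.to_numpy()[mask]
        pred = self._insample.values.to_numpy()[mask]
        self.nobs = int(mask.sum())
        ss_res = float(((obs - pred) ** 2).sum())
        self.rmse = float(np.sqrt(ss_res / self.nobs))
        if obs.std() > 0 and pred.std() > 0:
            self.pearson_r = float(np.corrcoef(obs, pred)[0, 1])
        else:
            self.pearson_r = float("nan")

    def predict(self, targets=None) -> PredictionResult:
        """Leave-target-out predictions for all (or the given) pairs."""
        return predict_loo(self.model.response, self.model.csn, self.model.dsn, self.params, targets)

    def predict_new(
        self, rho_sample=None, sample_profile=None, basis: FeatureMatrix | None = None,
        drugs=None, sample_id: str = "sample",
    ) -> PredictionResult:
        """Predict a new sample from either a precomputed similarity vector
        or a pathway-activity profile plus the training basis."""
        if rho_sample is None:
            if sample_profile is None or basis is None:
                raise ValueError("supply rho_sample, or sample_profile together with basis")
            rho_sample = similarity_to_training(sample_profile, basis)
        return predict_new(
            rho_sample, self.model.response, self.model.dsn, self.params, drugs, sample_id
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        from statsmodels.iolib.table import SimpleTable

        resp = self.model.response
        rows = [
            ("Cell lines", f"{len(resp.cell_ids)}"),
            ("Drugs", f"{len(resp.drug_ids)}"),
            ("Observed pairs", f"{self.nobs}"),
            ("CSN layer", f"{self.model.csn.layer_label} ({self.model.csn.measure})"),
            ("DSN layer", f"{self.model.dsn.layer_label} ({self.model.dsn.measure})"),
            ("sigma (cell decay)", f"{self.params.sigma:.4g}"),
            ("tau (drug decay)", f"{self.params.tau:.4g}"),
            ("J (SSE at optimum)", f"{self.j_best:.6g}"),
            ("In-sample Pearson r", f"{self.pearson_r:.4f}"),
            ("In-sample RMSE", f"{self.rmse:.4f}"),
        ]
        table = SimpleTable(
            [[v] for _, v in rows],
            headers=["value"],
            stubs=[k for k, _ in rows],
            title="ML-CDN fit (exhaustive decay-parameter grid search)",
        )
        return table.as_text()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MLCDNResults(sigma={self.params.sigma}, tau={self.params.tau}, "
            f"J={self.j_best:.4g}, r={self.pearson_r:.3f}, rmse={self.rmse:.3f})"
        )
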