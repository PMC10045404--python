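"""Presence-only maximum-entropy species distribution model.

The model is an exponential (Gibbs) density over background locations,
``p(x) ∝ exp(sum_j coef_j f_j(x))``, fit by maximizing the L1-penalized
presence log-likelihood — the classic maxent-as-penalized-GLM equivalence.
Features are constructed from named predictor columns: linear (L), quadratic
(Q), product (P), threshold (T) and hinge (H) classes, all rescaled to [0, 1]
over the background sample.  Each feature carries a penalty
``RM * beta_class * sd_j / sqrt(n_presence)``, so the regularization
multiplier RM scales model complexity globally.

Fitting uses cyclic coordinate descent with soft thresholding; the gain
increments attributed to each predictor during the descent provide percent
contributions, and permutation of predictor columns provides permutation
importance.  Model selection follows the standard presence-only tuning
protocol: a grid of RM values x feature-class combinations evaluated by AICc
(on the presence likelihood, k = nonzero coefficients) together with
spatial-block cross-validated AUC difference and 10% training omission rate.

Also provided: greedy pairwise-correlation variable filtering, jackknife
variable importance, response curves, Horn-method slope/aspect from elevation,
great-circle occurrence thinning and spatial-block fold assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MaxentFeatures",
    "MaxentModel",
    "fit_maxent",
    "predict_suitability",
    "build_env_table",
    "collinearity_filter",
    "derive_topography",
    "spatial_block_folds",
    "auc",
    "or10",
    "aicc",
    "tune_models",
    "jackknife_importance",
    "variable_contributions",
    "response_curve",
    "thin_occurrences",
    "DEFAULT_RM_VALUES",
    "DEFAULT_FEATURE_SETS",
]

DEFAULT_RM_VALUES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DEFAULT_FEATURE_SETS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")

#: base penalty per feature class (scaled by RM and feature s.d.)
_CLASS_BETA = {"L": 1.0, "Q": 1.0, "P": 1.0, "T": 1.0, "H": 0.5}

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# feature construction


@dataclass
class MaxentFeatures:
    """Feature definitions derived from a background sample.

    Each definition is a dict with ``kind`` in {L, Q, P, T, Hf, Hr}, source
    variable(s) and the scaling constants needed to re-apply the transform to
    new data.  ``transform`` maps a predictor DataFrame to the (n, k) feature
    matrix in [0, 1] (background range).
    """

    predictors: list
    defs: list

    @classmethod
    def build(cls, background: pd.DataFrame, predictors: list[str], classes: str,
              n_hinge_knots: int = 20, n_threshold_knots: int = 10) -> "MaxentFeatures":
        classes = set(classes.upper())
        unknown = classes - set("LQHPT")
        if unknown:
            raise ValueError(f"unknown feature class(es): {', '.join(sorted(unknown))}")
        defs = []
        stats = {v: (float(background[v].min()), float(background[v].max()))
                 for v in predictors}
        for v in predictors:
            lo, hi = stats[v]
            span = (hi - lo) or 1.0
            if "L" in classes:
                defs.append({"kind": "L", "var": v, "lo": lo, "span": span})
            if "Q" in classes:
                x2 = background[v].values.astype(float) ** 2
                qlo, qhi = float(x2.min()), float(x2.max())
                defs.append({"kind": "Q", "var": v, "lo": qlo, "span": (qhi - qlo) or 1.0})
            if "T" in classes and hi > lo:
                knots = np.quantile(background[v].values,
                                    np.linspace(0, 1, n_threshold_knots + 2)[1:-1])
                for k in np.unique(knots):
                    defs.append({"kind": "T", "var": v, "knot": float(k)})
            if "H" in classes and hi > lo:
                knots = np.quantile(background[v].values,
                                    np.linspace(0, 1, n_hinge_knots + 2)[1:-1])
                for k in np.unique(knots):
                    k = float(k)
                    if k < hi:
                        defs.append({"kind": "Hf", "var": v, "knot": k, "span": hi - k})
                    if k > lo:
                        defs.append({"kind": "Hr", "var": v, "knot": k, "span": k - lo})
        if "P" in classes:
            for i, v1 in enumerate(predictors):
                for v2 in predictors[i + 1:]:
                    prod = (background[v1].values * background[v2].values).astype(float)
                    plo, phi = float(prod.min()), float(prod.max())
                    defs.append({"kind": "P", "var": v1, "var2": v2,
                                 "lo": plo, "span": (phi - plo) or 1.0})
        return cls(list(predictors), defs)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for d in self.defs:
            x = df[d["var"]].values.astype(float)
            kind = d["kind"]
            if kind == "L":
                cols.append((x - d["lo"]) / d["span"])
            elif kind == "Q":
                cols.append((x ** 2 - d["lo"]) / d["span"])
            elif kind == "P":
                cols.append((x * df[d["var2"]].values - d["lo"]) / d["span"])
            elif kind == "T":
                cols.append((x > d["knot"]).astype(float))
            elif kind == "Hf":
                cols.append(np.clip((x - d["knot"]) / d["span"], 0.0, None))
            elif kind == "Hr":
                cols.append(np.clip((d["knot"] - x) / d["span"], 0.0, None))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def feature_vars(self) -> list:
        """Source variable(s) per feature, for gain attribution."""
        return [(d["var"], d.get("var2")) for d in self.defs]


# ---------------------------------------------------------------------------
# model


@dataclass
class MaxentModel:
    """Fitted penalized maxent model.

    ``alpha`` normalizes the raw density over the training background and
    ``entropy`` is the entropy of that density, used by the cloglog output
    transform.  ``contributions`` holds the per-predictor share of gain
    improvements accumulated during coordinate descent.
    """

    features: MaxentFeatures
    coefs: np.ndarray
    rm: float
    classes: str
    alpha: float
    entropy: float
    gain: float
    contributions: dict
    converged: bool = True
    n_iter: int = 0

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefs))

    def raw(self, df: pd.DataFrame) -> np.ndarray:
        """Relative occurrence rate, normalized to sum to 1 over the training background."""
        return np.exp(self.features.transform(df) @ self.coefs + self.alpha)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Cloglog-transformed suitability in [0, 1]."""
        return 1.0 - np.exp(-np.exp(self.entropy) * self.raw(df))

    def save(self, path: str | Path) -> None:
        payload = {
            "predictors": self.features.predictors,
            "defs": self.features.defs,
            "coefs": self.coefs.tolist(),
            "rm": self.rm, "classes": self.classes,
            "alpha": self.alpha, "entropy": self.entropy, "gain": self.gain,
            "contributions": self.contributions,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        feats = MaxentFeatures(d["predictors"], d["defs"])
        return cls(feats, np.asarray(d["coefs"], float), d["rm"], d["classes"],
                   d["alpha"], d["entropy"], d["gain"], d["contributions"])


def _fit_penalized(F_pres: np.ndarray, F_bg: np.ndarray, betas: np.ndarray,
                   feature_vars: list, tol: float = 1e-7, max_iter: int = 10000):
    """Cyclic coordinate descent on the penalized presence/background likelihood.

    Maximizes ``mean_pres(eta) - log mean_bg(exp(eta)) - sum_j beta_j |coef_j|``.
    Returns (coefs, gain, per-variable gain increments, converged, n_updates).
    """
    n_feat = F_pres.shape[1]
    coefs = np.zeros(n_feat)
    fbar = F_pres.mean(axis=0)
    eta = np.zeros(F_bg.shape[0])
    contrib: dict = {}
    n_updates = 0
    converged = False

    def gain_of(eta_bg, cf):
        m = eta_bg.max()
        return float(fbar @ cf - (m + np.log(np.exp(eta_bg - m).mean())))

    last_gain = 0.0
    while n_updates < max_iter:
        max_delta = 0.0
        for j in range(n_feat):
            m = eta.max()
            w = np.exp(eta - m)
            w /= w.sum()
            fj = F_bg[:, j]
            mu = w @ fj
            var = w @ (fj - mu) ** 2
            if var < 1e-12:
                continue
            g = fbar[j] - mu
            z = coefs[j] + g / var
            new = np.sign(z) * max(0.0, abs(z) - betas[j] / var)
            delta = np.clip(new - coefs[j], -1.0, 1.0)  # damp large Newton steps
            if delta == 0.0:
                continue
            coefs[j] += delta
            eta = eta + delta * fj
            n_updates += 1
            max_delta = max(max_delta, abs(delta))
            g_now = gain_of(eta, coefs)
            inc = g_now - last_gain
            last_gain = g_now
            if inc > 0:
                v1, v2 = feature_vars[j]
                if v2 is None:
                    contrib[v1] = contrib.get(v1, 0.0) + inc
                else:
                    contrib[v1] = contrib.get(v1, 0.0) + inc / 2.0
                    contrib[v2] = contrib.get(v2, 0.0) + inc / 2.0
        if max_delta < tol:
            converged = True
            break
    return coefs, last_gain, contrib, converged, n_updates


def fit_maxent(env: pd.DataFrame, predictors: list[str], classes: str = "LQH",
               rm: float = 1.0, n_hinge_knots: int = 20, n_threshold_knots: int = 10,
               tol: float = 1e-7, max_iter: int = 10000) -> MaxentModel:
    """Fit a penalized maxent model on an environment table.

    ``env`` holds presence and background rows (boolean ``presence`` column)
    with predictor columns; background rows define feature scaling and the
    normalizing density.
    """
    pres = env[env["presence"].astype(bool)]
    bg = env[~env["presence"].astype(bool)]
    if len(pres) < 2:
        raise ValueError("need at least 2 presence records")
    if len(bg) < 10:
        raise ValueError("need at least 10 background records")
    feats = MaxentFeatures.build(bg, predictors, classes,
                                 n_hinge_knots=n_hinge_knots,
                                 n_threshold_knots=n_threshold_knots)
    F_pres = feats.transform(pres)
    F_bg = feats.transform(bg)
    sd = F_pres.std(axis=0, ddof=0)
    sd = np.maximum(sd, 1e-3)  # floor keeps near-constant features finite
    class_beta = np.array([_CLASS_BETA[d["kind"][0]] for d in feats.defs])
    betas = rm * class_beta * sd / np.sqrt(len(pres))

    coefs, gain, contrib, converged, n_updates = _fit_penalized(
        F_pres, F_bg, betas, feats.feature_vars(), tol=tol, max_iter=max_iter)

    eta_bg = F_bg @ coefs
    m = eta_bg.max()
    alpha = -(m + np.log(np.exp(eta_bg - m).sum()))
    raw_bg = np.exp(eta_bg + alpha)
    nz = raw_bg > 0
    entropy = float(-(raw_bg[nz] * np.log(raw_bg[nz])).sum())
    return MaxentModel(feats, coefs, rm, classes, float(alpha), entropy, gain,
                       contrib, converged, n_updates)


def predict_suitability(model: MaxentModel, env: pd.DataFrame) -> np.ndarray:
    """Cloglog suitability in [0, 1] for the rows of ``env``."""
    return model.predict(env)


# ---------------------------------------------------------------------------
# evaluation metrics


def auc(pos_scores, neg_scores) -> float:
    """Rank-based AUC: probability a positive outscores a negative, ties 0.5."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def or10(train_presence_scores, test_presence_scores) -> float:
    """10% training omission rate.

    The threshold is the training-presence score just above the lowest 10%
    (ceiling rule on the count); OR10 is the fraction of test presences scoring
    strictly below it.
    """
    train = np.sort(np.asarray(train_presence_scores, float))
    test = np.asarray(test_presence_scores, float)
    if train.size == 0 or test.size == 0:
        raise ValueError("score sets must be non-empty")
    idx = min(int(np.ceil(0.1 * train.size)), train.size - 1)
    thr = train[idx]
    return float(np.mean(test < thr))


def aicc(model: MaxentModel, presence_env: pd.DataFrame) -> float:
    """Small-sample corrected AIC on the presence likelihood.

    k = count of nonzero coefficients, n = presences; the likelihood uses the
    raw density normalized over the training background.  Returns NaN when
    n <= k + 1 (the correction is undefined; such models are excluded from
    selection).
    """
    k = model.n_nonzero
    n = len(presence_env)
    if n <= k + 1:
        return float("nan")
    lnL = float(np.log(model.raw(presence_env)).sum())
    return 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (n - k - 1)


def spatial_block_folds(points: pd.DataFrame, k: int = 4,
                        medians: tuple[float, float] | None = None) -> np.ndarray:
    """Assign each (lon, lat) point to one of four lat/lon quadrant blocks.

    The split is at the coordinate medians (or the supplied ones, so background
    points can reuse presence-derived blocks).  Only k=4 is supported.
    """
    if k != 4:
        raise ValueError("only the 2x2 quadrant split (k=4) is supported")
    lon = points["lon"].values.astype(float)
    lat = points["lat"].values.astype(float)
    if np.ptp(lon) == 0 and np.ptp(lat) == 0:
        raise ValueError("all points identical: spatial blocks are degenerate")
    if medians is None:
        medians = (float(np.median(lon)), float(np.median(lat)))
    mlon, mlat = medians
    return ((lat > mlat).astype(int) * 2 + (lon > mlon).astype(int))


# ---------------------------------------------------------------------------
# tuning


def tune_models(env: pd.DataFrame, predictors: list[str],
                rm_values=DEFAULT_RM_VALUES, feature_sets=DEFAULT_FEATURE_SETS,
                folds: np.ndarray | None = None, **fit_kwargs):
    """Evaluate every RM x feature-class combination; select the minimum AICc.

    Each combination is fit on all data for AICc and cross-validated over
    spatial-block folds for avg AUC.DIFF and avg OR10.  Returns
    (results DataFrame, selected row as dict).
    """
    is_pres = env["presence"].astype(bool).values
    if folds is None:
        pres_pts = env[is_pres]
        med = (float(np.median(pres_pts["lon"])), float(np.median(pres_pts["lat"])))
        folds = spatial_block_folds(env, medians=med)
    folds = np.asarray(folds)

    rows = []
    for fc in feature_sets:
        for rm in rm_values:
            model = fit_maxent(env, predictors, classes=fc, rm=rm, **fit_kwargs)
            a = aicc(model, env[is_pres])
            diffs, ors = [], []
            for f in np.unique(folds):
                tr = env[(folds != f)]
                te_pres = env[(folds == f) & is_pres]
                te_bg = env[(folds == f) & ~is_pres]
                if te_pres.empty or te_bg.empty or tr["presence"].sum() < 2:
                    continue
                m = fit_maxent(tr, predictors, classes=fc, rm=rm, **fit_kwargs)
                tr_pres_scores = m.predict(tr[tr["presence"].astype(bool)])
                tr_bg_scores = m.predict(tr[~tr["presence"].astype(bool)])
                te_pres_scores = m.predict(te_pres)
                te_bg_scores = m.predict(te_bg)
                train_auc = auc(tr_pres_scores, tr_bg_scores)
                test_auc = auc(te_pres_scores, te_bg_scores)
                diffs.append(train_auc - test_auc)
                ors.append(or10(tr_pres_scores, te_pres_scores))
            rows.append({
                "rm": rm, "fc": fc, "aicc": a,
                "avg_auc_diff": float(np.mean(diffs)) if diffs else float("nan"),
                "avg_or10": float(np.mean(ors)) if ors else float("nan"),
                "n_nonzero": model.n_nonzero,
            })
    results = pd.DataFrame(rows)
    finite = results["aicc"].notna()
    if not finite.any():
        raise ValueError("AICc undefined for every combination (too few presences)")
    results["delta_aicc"] = results["aicc"] - results.loc[finite, "aicc"].min()
    best = results.loc[results.loc[finite, "aicc"].idxmin()]
    return results, best.to_dict()


# ---------------------------------------------------------------------------
# variable screening and importance


def collinearity_filter(env: pd.DataFrame, contributions: dict,
                        predictors: list[str] | None = None,
                        r_thresh: float = 0.8) -> list:
    """Greedy pairwise-correlation screen.

    Candidates are visited in descending contribution (ties by name); a
    variable is kept only if its |Pearson r| with every already-kept variable
    is <= ``r_thresh``, so of each offending pair the lower-contribution
    variable is dropped.
    """
    if predictors is None:
        predictors = [c for c in env.columns if c in contributions]
    missing = [v for v in predictors if v not in contributions]
    if missing:
        raise ValueError(f"no contribution value for: {', '.join(missing)}")
    order = sorted(predictors, key=lambda v: (-contributions[v], v))
    corr = env[predictors].corr().abs()
    kept: list = []
    for v in order:
        if all(corr.loc[v, u] <= r_thresh for u in kept):
            kept.append(v)
    return kept


def jackknife_importance(env: pd.DataFrame, predictors: list[str],
                         classes: str = "LQH", rm: float = 1.0,
                         **fit_kwargs) -> pd.DataFrame:
    """Regularized training gain with each variable alone and with it left out.

    Returns a DataFrame (variable, gain_only, gain_without, gain_full).
    """
    full = fit_maxent(env, predictors, classes=classes, rm=rm, **fit_kwargs).gain
    rows = []
    for v in predictors:
        only = fit_maxent(env, [v], classes=classes, rm=rm, **fit_kwargs).gain
        rest = [u for u in predictors if u != v]
        without = (fit_maxent(env, rest, classes=classes, rm=rm, **fit_kwargs).gain
                   if rest else 0.0)
        rows.append({"variable": v, "gain_only": only, "gain_without": without,
                     "gain_full": full})
    return pd.DataFrame(rows)


def variable_contributions(model: MaxentModel, env: pd.DataFrame,
                           seed: int = 0) -> pd.DataFrame:
    """Percent contribution (from the fitting trace) and permutation importance.

    Permutation importance is the drop in training AUC when one predictor's
    values are shuffled across all rows, clipped at zero and normalized to 100.
    """
    rng = np.random.default_rng(seed)
    is_pres = env["presence"].astype(bool).values
    base_scores = model.predict(env)
    auc0 = auc(base_scores[is_pres], base_scores[~is_pres])
    total_contrib = sum(model.contributions.values()) or 1.0
    rows = []
    drops = {}
    for v in model.features.predictors:
        shuffled = env.copy()
        shuffled[v] = rng.permutation(shuffled[v].values)
        s = model.predict(shuffled)
        drops[v] = max(0.0, auc0 - auc(s[is_pres], s[~is_pres]))
    total_drop = sum(drops.values()) or 1.0
    for v in model.features.predictors:
        rows.append({
            "variable": v,
            "percent_contribution": 100.0 * model.contributions.get(v, 0.0) / total_contrib,
            "permutation_importance": 100.0 * drops[v] / total_drop,
        })
    return pd.DataFrame(rows)


def response_curve(model: MaxentModel, variable: str, env: pd.DataFrame,
                   n_points: int = 100):
    """Predicted suitability sweeping one variable over its background range,
    all other predictors held at their background means."""
    bg = env[~env["presence"].astype(bool)] if "presence" in env else env
    x = np.linspace(bg[variable].min(), bg[variable].max(), n_points)
    probe = pd.DataFrame({v: np.full(n_points, bg[v].mean())
                          for v in model.features.predictors})
    probe[variable] = x
    return x, model.predict(probe)


# ---------------------------------------------------------------------------
# geography helpers


def derive_topography(elev: np.ndarray, lats: np.ndarray, lons: np.ndarray):
    """Slope (degrees) and downhill-facing aspect (degrees, 0=N, flat→0) from an
    elevation grid (meters) via Horn's 3x3 finite differences."""
    elev = np.asarray(elev, float)
    if elev.ndim != 2 or min(elev.shape) < 2:
        raise ValueError("elevation grid must be at least 2x2")
    res_lat = abs(lats[1] - lats[0]) if len(lats) > 1 else abs(lons[1] - lons[0])
    res_lon = abs(lons[1] - lons[0]) if len(lons) > 1 else res_lat
    dy = 110540.0 * res_lat  # meters per latitude step
    dx = 111320.0 * res_lon * np.cos(np.radians(np.asarray(lats)))[:, None]

    z = np.pad(elev, 1, mode="edge")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    # rows ascend in latitude, so "north" is the +row direction
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx)
    gy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dy)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect[slope == 0] = 0.0
    return slope, aspect


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def thin_occurrences(points: pd.DataFrame, min_km: float, seed: int = 0) -> pd.DataFrame:
    """Greedy distance thinning: repeatedly drop the point with the most
    neighbours closer than ``min_km`` (ties broken by seeded random choice)
    until no retained pair is closer than ``min_km``."""
    pts = points.drop_duplicates(subset=["lon", "lat"]).reset_index(drop=True)
    if np.any((pts["lat"] < -90) | (pts["lat"] > 90)):
        raise ValueError("latitude outside [-90, 90]")
    rng = np.random.default_rng(seed)
    lon = pts["lon"].values
    lat = pts["lat"].values
    dist = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    close = (dist < min_km) & ~np.eye(len(pts), dtype=bool)
    alive = np.ones(len(pts), bool)
    while True:
        deg = (close & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        alive[rng.choice(worst)] = False
    return pts[alive].reset_index(drop=True)


def build_env_table(rasters, occurrences: pd.DataFrame, predictors: list[str],
                    n_background: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Assemble the presence + background table from predictor rasters.

    ``rasters`` is an xarray Dataset with 2-D (lat, lon) predictor variables.
    Background locations are sampled uniformly (seeded, without replacement up
    to the cell count) over valid cells; presences are looked up at the nearest
    cell center.
    """
    lats = rasters["lat"].values
    lons = rasters["lon"].values
    valid = np.ones((lats.size, lons.size), bool)
    for v in predictors:
        valid &= np.isfinite(rasters[v].values)
    cells = np.flatnonzero(valid.ravel())
    rng = np.random.default_rng(seed)
    n_bg = min(n_background, cells.size)
    bg_cells = rng.choice(cells, size=n_bg, replace=False)
    bi, bj = np.unravel_index(bg_cells, valid.shape)

    pi = np.abs(occurrences["lat"].values[:, None] - lats[None, :]).argmin(axis=1)
    pj = np.abs(occurrences["lon"].values[:, None] - lons[None, :]).argmin(axis=1)

    def rows(ii, jj, presence):
        data = {"lon": lons[jj], "lat": lats[ii], "presence": presence}
        for v in predictors:
            data[v] = rasters[v].values[ii, jj]
        return pd.DataFrame(data)

    env = pd.concat([rows(pi, pj, True), rows(bi, bj, False)], ignore_index=True)
    if env[predictors].isna().any().any():
        raise ValueError("missing predictor values in environment table")
    return env
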