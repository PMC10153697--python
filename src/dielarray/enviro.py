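"""Environmental analysis: mixed-layer depth from CTD density profiles,
NMDS ordination of transcript profiles, environmental vector fitting with
permutation significance, and gene-environment correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import MDS

__all__ = [
    "mld_from_ctd",
    "Ordination",
    "nmds",
    "EnvFitResult",
    "envfit",
    "env_gene_correlations",
    "read_ctd",
]


def read_ctd(path) -> pd.DataFrame:
    """Load a CTD table (CSV with cast/pressure/variable columns)."""
    return pd.read_csv(path, index_col=0)


def mld_from_ctd(profile, offset: float = 0.03, ref_pressure: float = 10.0
                 ) -> tuple[float, bool]:
    """Mixed-layer depth: first pressure where potential density exceeds
    its reference-depth value by ``offset`` (kg/m^3), linearly interpolated.

    ``profile`` is an iterable of (pressure, sigma_theta) or a DataFrame
    with those columns.  Returns (depth in dbar, reached flag); when the
    threshold is never reached the deepest pressure is returned with
    ``reached=False``.
    """
    if isinstance(profile, pd.DataFrame):
        p = profile["pressure"].to_numpy(float)
        s = profile["sigma_theta"].to_numpy(float)
    else:
        arr = np.asarray(list(profile), float)
        p, s = arr[:, 0], arr[:, 1]
    order = np.argsort(p)
    p, s = p[order], s[order]
    if not np.isfinite(s).all():
        raise ValueError("sigma_theta values must be finite")
    if p[0] > ref_pressure or p[-1] < ref_pressure:
        raise ValueError("profile does not cover the reference pressure")
    sigma_ref = float(np.interp(ref_pressure, p, s))
    threshold = sigma_ref + offset
    below = p >= ref_pressure
    pb, sb = p[below], s[below]
    exceed = np.flatnonzero(sb >= threshold)
    if exceed.size == 0:
        return float(p[-1]), False
    i = exceed[0]
    if i == 0 or sb[i] == threshold:
        return float(pb[i]), True
    # interpolate between the bounding records
    frac = (threshold - sb[i - 1]) / (sb[i] - sb[i - 1])
    return float(pb[i - 1] + frac * (pb[i] - pb[i - 1])), True


@dataclass
class Ordination:
    """2-D NMDS solution with its Kruskal stress-1."""

    ids: pd.Index
    coords: np.ndarray         # n_points x 2
    stress: float
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.ids,
                            columns=["NMDS1", "NMDS2"])


def nmds(points: pd.DataFrame, distance: str = "euclidean", dims: int = 2,
         n_starts: int = 8, seed: int = 0, max_iter: int = 300) -> Ordination:
    """Non-metric MDS of row vectors (Kruskal stress-1, multiple starts).

    ``points`` is a points x features matrix (e.g. genes x samples of
    transcript levels); pass ``distance='precomputed'`` to supply a
    square dissimilarity matrix instead.
    """
    if points.shape[0] < 4:
        raise ValueError("NMDS needs >= 4 points")
    if distance == "precomputed":
        d = points.to_numpy(float)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(points.to_numpy(float)))
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    if np.allclose(d, 0.0):
        # degenerate: identical points embed at the origin with zero stress
        return Ordination(points.index, np.zeros((points.shape[0], dims)),
                          0.0, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(n_components=dims, metric_mds=False, metric="precomputed",
                    n_init=n_starts, max_iter=max_iter, init="random",
                    normalized_stress=True, random_state=seed)
        coords = model.fit_transform(d)
    return Ordination(points.index, coords, float(model.stress_), seed)


@dataclass(frozen=True)
class EnvFitResult:
    """One environmental variable fitted onto ordination coordinates."""

    variable: str
    direction: tuple[float, float]   # direction cosines of the fitted vector
    r_squared: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _fit_r2(coords: np.ndarray, v: np.ndarray) -> tuple[float, np.ndarray]:
    vc = v - v.mean()
    beta, *_ = np.linalg.lstsq(coords, vc, rcond=None)
    fitted = coords @ beta
    ss_tot = float(vc @ vc)
    ss_res = float((vc - fitted) @ (vc - fitted))
    return 1.0 - ss_res / ss_tot, beta


def envfit(ordination: Ordination, env: pd.DataFrame, n_perm: int = 999,
           seed: int = 0) -> pd.DataFrame:
    """Fit each environmental variable onto the ordination by least squares.

    r^2 is the squared multiple correlation of the (centered) variable
    with the 2-D coordinates; significance comes from permuting the
    variable across points, with the add-one correction
    ``p = (1 + #{permuted r^2 >= observed}) / (n_perm + 1)``.
    """
    env = env.loc[ordination.ids] if not env.index.equals(ordination.ids) else env
    coords = ordination.coords - ordination.coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    results = []
    for var in env.columns:
        v = env[var].to_numpy(float)
        if np.std(v) == 0:
            raise ValueError(f"environmental variable {var!r} is constant")
        r2, beta = _fit_r2(coords, v)
        norm = np.linalg.norm(beta)
        direction = tuple(beta / norm) if norm > 0 else (0.0, 0.0)
        n_ge = 0
        for _ in range(n_perm):
            r2p, _ = _fit_r2(coords, rng.permutation(v))
            if r2p >= r2:
                n_ge += 1
        p = (1 + n_ge) / (n_perm + 1)
        results.append(EnvFitResult(var, direction, float(r2), float(p)))
    return pd.DataFrame(
        [{"variable": r.variable, "dir1": r.direction[0], "dir2": r.direction[1],
          "r_squared": r.r_squared, "p_value": r.p_value,
          "significant": r.significant} for r in results]).set_index("variable")


def env_gene_correlations(expr_on_grid: pd.DataFrame, ctd: pd.DataFrame,
                          groups: pd.DataFrame | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pearson correlation of each gene's time series with each CTD variable.

    ``expr_on_grid`` is genes x time points (replicates already averaged
    onto the cast grid); ``ctd`` is time points x variables, aligned by
    column/index order.  ``groups`` optionally assigns genes to groups
    (e.g. diel/non-diel x sublineage) for per-group median correlations.
    """
    if expr_on_grid.shape[1] != ctd.shape[0]:
        raise ValueError("expression grid and CTD series differ in length")
    if expr_on_grid.shape[1] < 3:
        raise ValueError("need >= 3 matched time points")
    rows = {}
    for var in ctd.columns:
        y = ctd[var].to_numpy(float)
        if np.std(y) == 0:
            rows[var] = pd.Series(np.nan, index=expr_on_grid.index)
            continue
        rows[var] = expr_on_grid.apply(
            lambda r: stats.pearsonr(r.to_numpy(float), y).statistic
            if np.std(r.to_numpy(float)) > 0 else np.nan, axis=1)
    per_gene = pd.DataFrame(rows)
    medians = None
    if groups is not None:
        key = groups.apply(lambda r: "/".join(str(v) for v in r), axis=1)
        medians = per_gene.groupby(key.reindex(per_gene.index)).median()
    return per_gene, medians
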