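"""Consensus-of-tests differential-metabolite detection.

Three two-group tests (Welch t, a moderated t with variance shrinkage
toward a pooled prior, and a seeded permutation t) are run per metabolite
on the aligned intensity matrix; a metabolite is called significant only
when every test in the panel falls below the significance level.  The
module also provides a retention-time/mass kernel-density surface on which
significant metabolites can be located.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aligner import AlignmentResult
from .core import ConfigurationError, ContractError, Dataset


@dataclass
class AbundanceMatrix:
    """Consensus x map intensity matrix with two-treatment column labels."""

    values: pd.DataFrame  # rows: consensus_id, cols: map_1..map_K, NaN = missing
    groups: dict[int, str]  # map index -> group label
    centres: pd.DataFrame  # consensus_id -> (centre_rt, centre_mz, size)
    min_per_group: int = 2

    @property
    def group_labels(self) -> tuple[str, str]:
        labels = sorted(set(self.groups.values()))
        return labels[0], labels[1]

    def group_columns(self, label: str) -> list[str]:
        return [f"map_{m}" for m, g in sorted(self.groups.items()) if g == label]

    @property
    def testable(self) -> pd.Series:
        """Rows with at least ``min_per_group`` observed values per group."""
        g1, g2 = self.group_labels
        n1 = self.values[self.group_columns(g1)].notna().sum(axis=1)
        n2 = self.values[self.group_columns(g2)].notna().sum(axis=1)
        return (n1 >= self.min_per_group) & (n2 >= self.min_per_group)


def build_matrix(
    alignment: AlignmentResult,
    dataset: Dataset,
    groups: Mapping[int, str],
    min_per_group: int = 2,
) -> AbundanceMatrix:
    """Assemble the consensus intensity matrix from an alignment.

    Every map must be assigned to one of exactly two groups; uncovered maps
    leave missing cells.
    """
    missing_maps = [m for m in range(1, dataset.n_maps + 1) if m not in groups]
    if missing_maps:
        raise ConfigurationError(f"maps without a group assignment: {missing_maps}")
    if len(set(groups.values())) != 2:
        raise ConfigurationError("groups must partition the maps into exactly two treatments")
    by_uid = dataset.by_uid
    cols = [f"map_{m}" for m in range(1, dataset.n_maps + 1)]
    data = np.full((len(alignment.consensuses), dataset.n_maps), np.nan)
    centres = []
    for cid, cons in enumerate(alignment.consensuses):
        for uid in cons.members:
            f = by_uid[uid]
            data[cid, f.map_index - 1] = f.intensity
        centres.append(
            {"centre_rt": cons.centre_rt, "centre_mz": cons.centre_mz, "size": cons.size}
        )
    values = pd.DataFrame(data, columns=cols)
    values.index.name = "consensus_id"
    return AbundanceMatrix(
        values=values,
        groups=dict(groups),
        centres=pd.DataFrame(centres),
        min_per_group=min_per_group,
    )


@contextmanager
def _quiet_nan_math():
    """Silence expected empty-slice/df<=0 warnings from untestable rows."""
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


# -- per-row two-group tests (matrix in, p-value vector out) --------------


def welch_t_test(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; NaN entries are omitted."""
    with _quiet_nan_math():
        n1 = np.sum(~np.isnan(x), axis=1)
        n2 = np.sum(~np.isnan(y), axis=1)
        m1, m2 = np.nanmean(x, axis=1), np.nanmean(y, axis=1)
        v1, v2 = np.nanvar(x, axis=1, ddof=1), np.nanvar(y, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(p), p, 1.0)


def moderated_t_test(x: np.ndarray, y: np.ndarray, prior_df: float = 4.0) -> np.ndarray:
    """Row-wise moderated t: pooled within-group variance shrunk toward the
    across-row mean variance with ``prior_df`` prior degrees of freedom."""
    with _quiet_nan_math():
        n1 = np.sum(~np.isnan(x), axis=1)
        n2 = np.sum(~np.isnan(y), axis=1)
        m1, m2 = np.nanmean(x, axis=1), np.nanmean(y, axis=1)
        v1, v2 = np.nanvar(x, axis=1, ddof=1), np.nanvar(y, axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        s2_prior = np.nanmean(s2)
        s2_mod = (prior_df * s2_prior + df * s2) / (prior_df + df)
        t = (m1 - m2) / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    return np.where(np.isfinite(p), p, 1.0)


def permutation_t_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Row-wise label-permutation test on the Welch t statistic.

    p = (1 + #{|t_perm| > |t_obs|}) / (1 + B); the same seeded label
    permutations are shared across rows, keeping runs reproducible.
    Exceedance is strict so that sign-symmetric ties (e.g. the group-swap
    relabelling, which always reproduces |t_obs| exactly) do not count:
    the attainable minimum is therefore 1 / (B + 1).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = x.shape[1], y.shape[1]
    pooled = np.concatenate([x, y], axis=1)
    obs = np.abs(_welch_t_stat(x, y))
    count = np.zeros(pooled.shape[0])
    for _ in range(n_permutations):
        perm = rng.permutation(n1 + n2)
        px, py = pooled[:, perm[:n1]], pooled[:, perm[n1:]]
        # tiny relative margin: summation order changes |t| by an ulp, which
        # must not turn a sign-symmetric tie into an exceedance
        count += np.abs(_welch_t_stat(px, py)) > obs * (1.0 + 1e-9) + 1e-12
    return (1.0 + count) / (1.0 + n_permutations)


def _welch_t_stat(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    with _quiet_nan_math():
        n1 = np.sum(~np.isnan(x), axis=1)
        n2 = np.sum(~np.isnan(y), axis=1)
        t = (np.nanmean(x, axis=1) - np.nanmean(y, axis=1)) / np.sqrt(
            np.nanvar(x, axis=1, ddof=1) / n1 + np.nanvar(y, axis=1, ddof=1) / n2
        )
    return np.where(np.isfinite(t), t, 0.0)


@dataclass
class TestPanel:
    """A named collection of row-wise two-group tests plus a significance level."""

    __test__ = False  # not a pytest collectable despite the name

    alpha: float = 0.001
    prior_df: float = 4.0
    n_permutations: int = 1000
    seed: int = 0
    extra_tests: list[tuple[str, Callable[[np.ndarray, np.ndarray], np.ndarray]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")

    def tests(self) -> list[tuple[str, Callable[[np.ndarray, np.ndarray], np.ndarray]]]:
        base = [
            ("welch_t", welch_t_test),
            (
                "moderated_t",
                lambda x, y: moderated_t_test(x, y, prior_df=self.prior_df),
            ),
            (
                "permutation_t",
                lambda x, y: permutation_t_test(
                    x, y, n_permutations=self.n_permutations, seed=self.seed
                ),
            ),
        ]
        return base + list(self.extra_tests)


def consensus_significant(
    matrix: AbundanceMatrix,
    panel: TestPanel | None = None,
    alpha: float | None = None,
    log2: bool = True,
) -> pd.DataFrame:
    """Run the panel and intersect the calls.

    Returns a per-metabolite table with one p-value column per test, the
    mean differential abundance (group 1 mean minus group 2 mean), a
    ``testable`` flag and a ``significant`` flag (every test p < alpha).
    Intensities are log2-transformed by default before testing.
    """
    panel = panel or TestPanel()
    alpha = panel.alpha if alpha is None else alpha
    g1, g2 = matrix.group_labels
    x = matrix.values[matrix.group_columns(g1)].to_numpy(dtype=float)
    y = matrix.values[matrix.group_columns(g2)].to_numpy(dtype=float)
    if log2:
        with np.errstate(divide="ignore"):
            x, y = np.log2(x), np.log2(y)
    testable = matrix.testable.to_numpy()
    out = pd.DataFrame(index=matrix.values.index.copy())
    with _quiet_nan_math():
        out["mean_diff"] = np.nanmean(x, axis=1) - np.nanmean(y, axis=1)
    significant = testable.copy()
    for name, test in panel.tests():
        p = np.where(testable, test(x, y), np.nan)
        out[f"p_{name}"] = p
        significant &= np.where(np.isnan(p), False, p < alpha)
    out["testable"] = testable
    out["significant"] = significant
    out["centre_rt"] = matrix.centres["centre_rt"].to_numpy()
    out["centre_mz"] = matrix.centres["centre_mz"].to_numpy()
    return out


def significant_set(table: pd.DataFrame) -> list[int]:
    """Consensus ids called significant by every test in the panel."""
    return table.index[table["significant"]].tolist()


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Optional BH-adjusted p-values (not applied by default)."""
    p = np.asarray(p, dtype=float)
    mask = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    pv = p[mask]
    n = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(pv)
    out[order] = np.clip(ranked, 0, 1)
    adj[mask] = out
    return adj


def rm_density_surface(
    dataset: Dataset,
    significant_centres: Sequence[tuple[float, float]] = (),
    grid: int = 100,
    margin: float = 0.15,
):
    """Kernel-density surface over feature (rt, mass) coordinates.

    Returns ``(rt_grid, mz_grid, density, overlay)`` where ``density`` is a
    ``grid x grid`` array normalized to integrate to 1 over the grid and
    ``overlay`` is the list of significant-metabolite coordinates.
    """
    if dataset.n_features == 0:
        raise ContractError("cannot build a density surface from no features")
    rts = np.array([f.rt for f in dataset.features])
    mzs = np.array([f.mz for f in dataset.features])

    def _axis(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        span = max(hi - lo, 1.0)
        return np.linspace(lo - margin * span, hi + margin * span, grid)

    rt_grid, mz_grid = _axis(rts), _axis(mzs)
    rr, mm = np.meshgrid(rt_grid, mz_grid, indexing="ij")
    pts = np.vstack([rr.ravel(), mm.ravel()])
    try:
        kde = stats.gaussian_kde(np.vstack([rts, mzs]))
        density = kde(pts).reshape(grid, grid)
    except (np.linalg.LinAlgError, ValueError):
        # degenerate sample (n < 3 or zero variance): isotropic Gaussian bumps
        h_rt = max(np.std(rts), 1.0)
        h_mz = max(np.std(mzs), 1.0)
        density = np.zeros((grid, grid))
        for rt, mz in zip(rts, mzs):
            density += np.exp(
                -0.5 * (((rr - rt) / h_rt) ** 2 + ((mm - mz) / h_mz) ** 2)
            ) / (2 * np.pi * h_rt * h_mz)
        density /= len(rts)
    integral = np.trapezoid(np.trapezoid(density, mz_grid, axis=1), rt_grid)
    density = density / integral
    return rt_grid, mz_grid, density, list(significant_centres)


def plot_surface(rt_grid, mz_grid, density, overlay, path) -> None:
    """Render the density surface with significant metabolites overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(rt_grid, mz_grid, density.T, levels=30, cmap="viridis")
    if overlay:
        orts, omzs = zip(*overlay)
        ax.plot(orts, omzs, "r.", markersize=6)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("mass (Da)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_volcano(table: pd.DataFrame, path, alpha: float = 0.001) -> None:
    """Mean differential abundance vs the worst (largest) panel p-value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p_cols = [c for c in table.columns if c.startswith("p_")]
    worst_p = table[p_cols].max(axis=1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["mean_diff"], worst_p, "k.", markersize=3)
    sig = table["significant"]
    for x in table.loc[sig, "mean_diff"]:
        ax.axvline(x, color="r", linewidth=0.6)
    ax.axhline(alpha, color="b", linestyle=":", linewidth=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("mean differential abundance")
    ax.set_ylabel("p value (max over panel)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
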