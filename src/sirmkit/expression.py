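"""Transcriptome gene selection with a resampling FDR estimate.

The procedure mirrors a three-replicate knock-down vs control design:

1. discard genes consistently below the per-sample median expression;
2. average technical replicates on the log2 scale;
3. z-transform per-experiment log2 fold changes with an intensity-dependent
   error model (rolling robust spread of fold change vs mean intensity);
4. select genes whose |z| sits in the top decile of every experiment with a
   consistent sign of regulation;
5. estimate the FDR of that selection by repeated random draws that break
   the gene linkage across experiments while preserving each experiment's
   marginal z distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826  # consistency factor: MAD of a normal -> its sd


@dataclass
class Experiment:
    """One knock-down vs control experiment: a gene x column log2 matrix.

    ``roles`` maps each column to 'sample' or 'control'; ``tech_groups``
    optionally maps columns to technical-replicate group labels.
    """

    name: str
    data: pd.DataFrame
    roles: Mapping[str, str]
    tech_groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        unknown = [c for c in self.data.columns if c not in self.roles]
        if unknown:
            raise ValueError(f"experiment {self.name}: columns without a role: {unknown}")
        bad = [c for c, r in self.roles.items() if r not in ("sample", "control")]
        if bad:
            raise ValueError(f"experiment {self.name}: roles must be sample/control, got {bad}")

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == role]


@dataclass
class ExperimentSet:
    """Experiments restricted to their shared gene universe."""

    experiments: list[Experiment]

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("ExperimentSet needs at least one experiment")
        common = self.experiments[0].data.index
        for exp in self.experiments[1:]:
            common = common.intersection(exp.data.index)
        if common.empty:
            raise ValueError("no genes shared across experiments")
        self.experiments = [
            Experiment(e.name, e.data.loc[common], dict(e.roles), e.tech_groups)
            for e in self.experiments
        ]

    @property
    def genes(self) -> pd.Index:
        return self.experiments[0].data.index

    def restrict(self, genes: pd.Index) -> "ExperimentSet":
        return ExperimentSet(
            [Experiment(e.name, e.data.loc[genes], dict(e.roles), e.tech_groups) for e in self.experiments]
        )


def filter_low_expression(eset: ExperimentSet) -> ExperimentSet:
    """Drop genes below the per-sample median in every sample of every experiment."""
    low_everywhere = pd.Series(True, index=eset.genes)
    for exp in eset.experiments:
        below = exp.data.lt(exp.data.median(axis=0), axis=1)
        low_everywhere &= below.all(axis=1)
    keep = eset.genes[~low_everywhere]
    if keep.empty:
        raise ValueError("low-expression filter removed every gene; review the threshold")
    return eset.restrict(keep)


def average_technical_replicates(eset: ExperimentSet) -> ExperimentSet:
    """Arithmetic mean on the log2 scale within technical-replicate groups."""
    out = []
    for exp in eset.experiments:
        if not exp.tech_groups:
            out.append(exp)
            continue
        groups: dict[str, list[str]] = {}
        for col in exp.data.columns:
            groups.setdefault(exp.tech_groups.get(col, col), []).append(col)
        data = pd.DataFrame({g: exp.data[cols].mean(axis=1) for g, cols in groups.items()})
        roles = {g: exp.roles[cols[0]] for g, cols in groups.items()}
        out.append(Experiment(exp.name, data, roles))
    return ExperimentSet(out)


def _rolling_mad(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median absolute deviation (exact, per window)."""
    s = pd.Series(values)
    return (
        s.rolling(window, center=True, min_periods=max(2, window // 2))
        .apply(lambda v: np.median(np.abs(v - np.median(v))), raw=True)
        .bfill()
        .ffill()
        .to_numpy()
    )


@dataclass
class ZScoreSet:
    """Per-experiment signed z values plus the fitted error model.

    Sign convention: positive z = up-regulated in the knock-down (sample)
    relative to control.
    """

    z: pd.DataFrame  # genes x experiments
    fold_change: pd.DataFrame
    sigma: pd.DataFrame  # fitted spread at each gene's mean intensity

    @property
    def experiments(self) -> list[str]:
        return list(self.z.columns)


def z_transform(
    eset: ExperimentSet,
    window: int = 200,
    sigma_table: Mapping[str, pd.Series] | None = None,
) -> ZScoreSet:
    """Error-model z-transformation of per-experiment log2 fold changes.

    The spread sigma(a) is the rolling MAD (x1.4826) of the fold change over
    a ``window`` of genes ranked by mean expression a; a user-supplied
    ``sigma_table`` (experiment -> gene-indexed sigma) overrides the rolling
    estimate to allow exact replication of other error models.
    """
    n_genes = len(eset.genes)
    if window > n_genes:
        raise ValueError(f"window {window} exceeds gene count {n_genes}")
    z_cols, fc_cols, sg_cols = {}, {}, {}
    for exp in eset.experiments:
        sample_cols = exp.columns_with_role("sample")
        control_cols = exp.columns_with_role("control")
        if not sample_cols or not control_cols:
            raise ValueError(f"experiment {exp.name} lacks a sample or control column")
        fc = exp.data[sample_cols].mean(axis=1) - exp.data[control_cols].mean(axis=1)
        if sigma_table is not None and exp.name in sigma_table:
            sigma = pd.Series(sigma_table[exp.name], index=eset.genes, dtype=float)
        else:
            intensity = exp.data.mean(axis=1)
            order = np.argsort(intensity.to_numpy(), kind="stable")
            mad = _rolling_mad(fc.to_numpy()[order], window)
            sigma_sorted = MAD_SCALE * mad
            sigma = pd.Series(index=eset.genes, dtype=float)
            sigma.iloc[order] = sigma_sorted
        safe = np.where(sigma.to_numpy() > 0, sigma.to_numpy(), np.inf)
        z = pd.Series(fc.to_numpy() / safe, index=eset.genes)
        z_cols[exp.name] = z
        fc_cols[exp.name] = fc
        sg_cols[exp.name] = sigma
    return ZScoreSet(pd.DataFrame(z_cols), pd.DataFrame(fc_cols), pd.DataFrame(sg_cols))


@dataclass
class SelectionResult:
    """Genes consistently in the top |z| fraction with one sign everywhere."""

    selected: pd.DataFrame  # index: genes; column 'sign' (+1/-1)
    thresholds: pd.Series  # per-experiment |z| decile threshold
    q: float

    @property
    def genes(self) -> pd.Index:
        return self.selected.index

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _as_z_frame(z) -> pd.DataFrame:
    return z.z if isinstance(z, ZScoreSet) else pd.DataFrame(z)


def select_consistent_top(z, q: float = 0.10) -> SelectionResult:
    """Select genes in the top ``q`` of |z| in *every* experiment, same sign.

    Thresholds are the inclusive (type-7) empirical (1-q) quantiles of |z|
    per experiment; boundary ties are selected (>= comparison).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    zf = _as_z_frame(z)
    absz = zf.abs()
    thresholds = absz.quantile(1.0 - q, interpolation="linear")
    in_top = absz.ge(thresholds, axis=1).all(axis=1)
    signs = np.sign(zf.to_numpy())
    consistent = (signs == signs[:, [0]]).all(axis=1)
    mask = in_top.to_numpy() & consistent
    selected = pd.DataFrame({"sign": signs[mask, 0].astype(int)}, index=zf.index[mask])
    return SelectionResult(selected, thresholds, q)


@dataclass
class FDRReport:
    """Resampling estimate of the selection's false-discovery rate.

    Each draw resamples every experiment's z values with replacement,
    independently per experiment — destroying the cross-experiment gene
    matching that real co-regulation induces — and re-runs the selection.
    FDR = mean null selection count / observed count, clipped to [0, 1];
    ``fdr`` is None when no genes were observed selected.
    """

    n_draws: int
    null_counts: np.ndarray
    observed: int
    fdr: float | None
    seed: int | None
    q: float = 0.10


def estimate_fdr(z, q: float = 0.10, n_draws: int = 1000, seed: int | None = None) -> FDRReport:
    """Random-draw FDR of ``select_consistent_top`` at top fraction ``q``."""
    zf = _as_z_frame(z)
    observed = select_consistent_top(zf, q).n_selected
    rng = np.random.default_rng(seed)
    n = len(zf.index)
    values = zf.to_numpy()
    null_counts = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        null = np.column_stack(
            [values[rng.integers(0, n, size=n), j] for j in range(values.shape[1])]
        )
        null_counts[d] = select_consistent_top(
            pd.DataFrame(null, columns=zf.columns), q
        ).n_selected
    if observed == 0:
        return FDRReport(n_draws, null_counts, 0, None, seed, q)
    fdr = float(np.clip(null_counts.mean() / observed, 0.0, 1.0))
    return FDRReport(n_draws, null_counts, observed, fdr, seed, q)


def sign_permutation_fdr(z, q: float = 0.10, n_draws: int = 1000, seed: int | None = None) -> FDRReport:
    """Alternative null: flip each gene's z sign per experiment at random."""
    zf = _as_z_frame(z)
    observed = select_consistent_top(zf, q).n_selected
    rng = np.random.default_rng(seed)
    values = zf.to_numpy()
    null_counts = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        flips = rng.choice([-1.0, 1.0], size=values.shape)
        null_counts[d] = select_consistent_top(
            pd.DataFrame(values * flips, columns=zf.columns), q
        ).n_selected
    if observed == 0:
        return FDRReport(n_draws, null_counts, 0, None, seed, q)
    fdr = float(np.clip(null_counts.mean() / observed, 0.0, 1.0))
    return FDRReport(n_draws, null_counts, observed, fdr, seed, q)


def rank_knockdown_target(z, gene: str) -> dict:
    """Rank of a gene among down-regulated genes (ascending z; rank 1 = most down).

    Returns per-experiment min-ranks, a pooled rank over the mean z across
    experiments, and a flag for ties at the gene's value.
    """
    zf = _as_z_frame(z)
    if gene not in zf.index:
        raise KeyError(f"gene {gene!r} not present")
    per_experiment = {}
    tied = False
    for col in zf.columns:
        ranks = zf[col].rank(method="min", ascending=True)
        per_experiment[col] = int(ranks.loc[gene])
        tied |= (zf[col] == zf.loc[gene, col]).sum() > 1
    pooled = zf.mean(axis=1).rank(method="min", ascending=True)
    return {
        "per_experiment": per_experiment,
        "pooled": int(pooled.loc[gene]),
        "tied": bool(tied),
    }
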