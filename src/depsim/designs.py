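"""Benchmark experiment designs built on a fitted reference model.

``inject_de`` perturbs a copy of the model to contain known
differential expression (a fraction of genes gets its base mean scaled
by 2^(+/-lfc)); ``with_group_means`` builds one model per experimental
group (e.g., circadian time point) that shares the baseline dependence
structure but swaps in per-group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copula import ReferenceModel

__all__ = ["DETruth", "GroupMeans", "inject_de", "with_group_means"]


@dataclass
class DETruth:
    """Ground truth of an injected differential-expression design."""

    gene_ids: np.ndarray
    lfc: np.ndarray  # signed log2 fold changes, one per flagged gene

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "lfc": self.lfc,
                "direction": np.where(self.lfc >= 0, "up", "down"),
            }
        )


@dataclass
class GroupMeans:
    """Per-group, per-gene base means (e.g., one column per time point)."""

    gene_ids: np.ndarray
    labels: list
    means: np.ndarray  # p x n_groups, nonnegative

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.gene_ids), len(self.labels)):
            raise ValueError("means must be genes x groups")
        if np.any(self.means < 0):
            raise ValueError("group means must be nonnegative")

    @classmethod
    def from_counts(
        cls,
        counts_values: np.ndarray,
        gene_ids: np.ndarray,
        group_of_sample: np.ndarray,
        size_factors: np.ndarray | None = None,
    ) -> "GroupMeans":
        """Group means of size-factor-normalized counts, per gene."""
        X = np.asarray(counts_values, dtype=float)
        if size_factors is not None:
            X = X / np.asarray(size_factors, dtype=float)
        labels = list(pd.unique(np.asarray(group_of_sample)))
        means = np.column_stack(
            [X[:, np.asarray(group_of_sample) == g].mean(axis=1) for g in labels]
        )
        return cls(gene_ids=np.asarray(gene_ids, dtype=object), labels=labels, means=means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.gene_ids, columns=self.labels)


def inject_de(
    model: ReferenceModel,
    fraction: float = 0.05,
    lfc_low: float = 0.2,
    lfc_high: float = 2.0,
    seed: int = 0,
    *,
    sign: str = "random",
) -> tuple[ReferenceModel, DETruth]:
    """Flag a random fraction of genes as differentially expressed.

    Each flagged gene's base mean is multiplied by 2^(+/-lfc) with
    |lfc| ~ U(lfc_low, lfc_high) and a fair-coin sign (``sign`` may
    force ``"up"`` or ``"down"``); dispersion and variance parameters
    are unchanged.  Only genes with base mean > 0 are eligible (scaling
    a zero mean is a no-op).  Defaults: 5% of genes, |lfc| in (0.2, 2.0).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not 0.0 <= lfc_low <= lfc_high:
        raise ValueError("need 0 <= lfc_low <= lfc_high")
    marg = model.marginals
    if marg.family == "empirical":
        raise ValueError(
            "empirical marginals have no mean parameter to scale; "
            "differential expression cannot be injected"
        )
    means = marg.base_means()
    eligible = np.flatnonzero(means > 0)
    n_de = int(round(fraction * len(eligible)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_de, replace=False) if n_de else np.empty(0, int)
    lfc = rng.uniform(lfc_low, lfc_high, size=n_de)
    if sign == "random":
        signs = rng.choice([-1.0, 1.0], size=n_de)
    elif sign in ("up", "down"):
        signs = np.full(n_de, 1.0 if sign == "up" else -1.0)
    else:
        raise ValueError("sign must be 'random', 'up' or 'down'")
    new_means = means.copy()
    new_means[chosen] = means[chosen] * 2.0 ** (signs * lfc)
    perturbed = model.replace_marginals(marg.with_base_means(new_means))
    truth = DETruth(gene_ids=model.gene_ids[chosen].copy(), lfc=signs * lfc)
    return perturbed, truth


def with_group_means(
    model: ReferenceModel, means: GroupMeans
) -> dict[object, ReferenceModel]:
    """One model per group, sharing the baseline dependence structure.

    Each returned model holds the *same* CovarianceFactors object as the
    baseline (dependence and dispersions are fit once, on the baseline
    group), with the base means replaced by the group's means.
    Simulating each group and concatenating yields a time-series design
    where samples are independent conditional on the group.
    """
    if not np.array_equal(means.gene_ids, model.gene_ids):
        missing = set(model.gene_ids) ^ set(means.gene_ids)
        raise ValueError(
            f"group means do not cover the model's gene set (or order); "
            f"offending ids: {sorted(missing)[:10]}"
        )
    out: dict[object, ReferenceModel] = {}
    for j, label in enumerate(means.labels):
        out[label] = model.replace_marginals(
            model.marginals.with_base_means(means.means[:, j])
        )
        assert out[label].factors is model.factors  # sharing contract
    return out
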