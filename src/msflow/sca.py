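"""Blockscaled Simultaneous Component Analysis (SCA).

SCA is the multi-set extension of PCA for column-linked data.  Before
the decomposition each sample block is *blockscaled* — divided by the
square root of its cell count — so that every sample contributes the
same total amount of variance to the loading estimate, no matter how
many cells it holds:

    X*_sc = [ X_sc,1 / sqrt(N_1) ; ... ; X_sc,I / sqrt(N_I) ]
    X*_sc = T* P*^T + E          (thin SVD, top K components)
    T     = X_sc P*              (scores of the unblockscaled data)

The loadings ``P*`` therefore describe marker co-variation balanced
across samples, while the scores ``T`` place every cell of every sample
on a common scale.  Without blockscaling the loadings are dominated by
the samples with the most cells, which is exactly the failure mode this
correction removes: the sample cross-products entering the loading
estimate become ``X_i^T X_i / N_i``, invariant under replicating a
sample's cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MultiSet, PanelMismatchError, concatenate

__all__ = ["blockscale", "SCA", "SCAResults", "fit_sca"]


def blockscale(ms: MultiSet) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate sample blocks, each divided by sqrt(its cell count)."""
    x = np.vstack([s.data / np.sqrt(s.n_cells) for s in ms.samples])
    index = pd.DataFrame(
        {
            "sample_id": np.repeat(ms.sample_ids, ms.n_cells),
            "group_id": np.repeat(ms.group_ids, ms.n_cells),
        }
    )
    return x, index


def _fix_column_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    signs = np.empty(loadings.shape[1])
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        signs[k] = 1.0 if loadings[j, k] >= 0 else -1.0
    return signs


class SCA:
    """Model object: blockscaled simultaneous component decomposition.

    Parameters
    ----------
    ms : MultiSet
        Preprocessed (transformed/centered/scaled) multi-set.
    n_components : int, optional
        Number of components K; defaults to ``min(J, 10)``.
    blockscaled : bool
        When False the decomposition runs on the raw concatenated matrix
        (an ablation mode that re-introduces the dependence of loadings
        on per-sample cell counts; useful for demonstrating why
        blockscaling matters, not for analysis).
    """

    def __init__(self, ms: MultiSet, n_components: int | None = None,
                 blockscaled: bool = True):
        self.ms = ms
        j = ms.n_markers
        max_k = min(j, int(ms.n_cells.sum()))
        if n_components is None:
            n_components = min(j, 10)
        if not 1 <= n_components <= max_k:
            raise ValueError(
                f"n_components must be in [1, {max_k}], got {n_components}"
            )
        self.n_components = int(n_components)
        self.blockscaled = bool(blockscaled)

    def fit(self) -> "SCAResults":
        ms, k = self.ms, self.n_components
        if self.blockscaled:
            xb, _ = blockscale(ms)
        else:
            xb, _ = concatenate(ms)
        # thin SVD is numerically preferable to forming X^T X
        _, svals, vt = np.linalg.svd(xb, full_matrices=False)
        loadings = vt[:k].T
        signs = _fix_column_signs(loadings)
        loadings = loadings * signs
        x, index = concatenate(ms)
        scores = x @ loadings
        total = float((svals ** 2).sum())
        evr = (svals[:k] ** 2) / total if total > 0 else np.zeros(k)
        residual = float(np.sqrt(max((svals[k:] ** 2).sum(), 0.0)))
        return SCAResults(
            panel=ms.panel,
            loadings=loadings,
            scores=scores,
            score_index=index,
            singular_values=svals[:k].copy(),
            all_singular_values=svals.copy(),
            explained_variance_ratio=evr,
            residual_norm=residual,
            blockscaled=self.blockscaled,
        )


@dataclass
class SCAResults:
    """Fitted SCA decomposition.

    Attributes
    ----------
    loadings : ndarray, (J, K)
        Orthonormal marker loadings ``P*`` of the blockscaled matrix,
        column signs fixed so the largest-magnitude entry is positive.
    scores : ndarray, (sum N_i, K)
        Per-cell scores ``T = X_sc P*`` of the *unblockscaled* data.
    singular_values : ndarray, (K,)
        Nonincreasing singular values of the blockscaled matrix.
    explained_variance_ratio : ndarray, (K,)
        Fraction of blockscaled variance captured per component.
    residual_norm : float
        Frobenius norm of the residual ``E`` of the blockscaled fit.
    """

    panel: object
    loadings: np.ndarray
    scores: np.ndarray
    score_index: pd.DataFrame
    singular_values: np.ndarray
    all_singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    residual_norm: float
    blockscaled: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, ms: MultiSet) -> np.ndarray:
        """Scores of (new or training) data in the fitted loading space.

        Projection needs no refit, so held-out samples of a
        cross-validation fold can be scored in the training space.
        """
        if ms.panel.names != self.panel.names:
            raise PanelMismatchError(
                f"panel mismatch: model {list(self.panel.names)} vs data "
                f"{list(ms.panel.names)}"
            )
        x, _ = concatenate(ms)
        return x @ self.loadings

    def biplot_tables(self, dims: tuple[int, int] = (1, 2)
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format score and loading tables for a component pair.

        ``dims`` are 1-based component indices.  Returns
        ``(scores_table, loadings_table)`` with one row per cell and one
        row per marker respectively.
        """
        k1, k2 = dims
        for d in (k1, k2):
            if not 1 <= d <= self.n_components:
                raise ValueError(
                    f"component index {d} out of range [1, {self.n_components}]"
                )
        scores = self.score_index.copy()
        scores[f"score_{k1}"] = self.scores[:, k1 - 1]
        scores[f"score_{k2}"] = self.scores[:, k2 - 1]
        loadings = pd.DataFrame(
            {
                "marker": list(self.panel.names),
                f"load_{k1}": self.loadings[:, k1 - 1],
                f"load_{k2}": self.loadings[:, k2 - 1],
            }
        )
        return scores, loadings

    def plot_biplot(self, dims: tuple[int, int] = (1, 2), ax=None,
                    max_cells: int = 20000, seed: int = 0):
        """Score scatter colored by group with loading arrows overlaid."""
        import matplotlib.pyplot as plt

        scores, loadings = self.biplot_tables(dims)
        if len(scores) > max_cells:
            rng = np.random.default_rng(seed)
            scores = scores.iloc[rng.choice(len(scores), max_cells,
                                            replace=False)]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        k1, k2 = dims
        for gid, sub in scores.groupby("group_id"):
            ax.scatter(sub[f"score_{k1}"], sub[f"score_{k2}"], s=3, alpha=0.3,
                       label=f"group {gid}")
        span = max(np.abs(scores[[f"score_{k1}", f"score_{k2}"]].to_numpy()).max(),
                   1e-12)
        for _, row in loadings.iterrows():
            ax.annotate(row["marker"],
                        xy=(row[f"load_{k1}"] * span, row[f"load_{k2}"] * span),
                        xytext=(0, 0), textcoords="data",
                        arrowprops=dict(arrowstyle="<-", color="black"))
        ax.set_xlabel(f"SCA component {k1} "
                      f"({100 * self.explained_variance_ratio[k1 - 1]:.1f}%)")
        ax.set_ylabel(f"SCA component {k2} "
                      f"({100 * self.explained_variance_ratio[k2 - 1]:.1f}%)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"Simultaneous Component Analysis "
            f"({'blockscaled' if self.blockscaled else 'NOT blockscaled'})",
            f"  cells x markers : {self.scores.shape[0]} x "
            f"{len(self.panel.names)}",
            f"  components      : {self.n_components}",
            f"  residual norm   : {self.residual_norm:.6g}",
            f"  {'component':<11}{'sing.value':>12}{'expl.var %':>12}"
            f"{'cum %':>9}",
        ]
        cum = 0.0
        for k in range(self.n_components):
            cum += self.explained_variance_ratio[k]
            lines.append(
                f"  {k + 1:<11}{self.singular_values[k]:>12.5g}"
                f"{100 * self.explained_variance_ratio[k]:>12.2f}"
                f"{100 * cum:>9.2f}"
            )
        return "\n".join(lines)


def fit_sca(ms: MultiSet, n_components: int | None = None,
            blockscaled: bool = True) -> SCAResults:
    """Functional alias for ``SCA(ms, n_components, blockscaled).fit()``."""
    return SCA(ms, n_components, blockscaled).fit()
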