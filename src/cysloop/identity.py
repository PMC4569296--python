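"""SDT-style pairwise percentage-identity matrices from a protein MSA.

Identity between two aligned rows is the percentage of identical-residue
columns among the columns where at least one row has a residue: columns
gapped in both rows are excluded, and a column gapped in exactly one row
counts as a mismatch (the Sequence Demarcation Tool convention).  An
optional neighbour-joining leaf ordering (distance = 100 - identity)
arranges the matrix for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GAPS = frozenset("-.")


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, diagonal 100

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def cell(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().round(2).to_csv(path, sep="\t")


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Percent identity between two aligned rows (SDT gap convention)."""
    if len(row_a) != len(row_b):
        raise ValueError(f"aligned lengths differ: {len(row_a)} vs {len(row_b)}")
    scored = ident = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        a_gap, b_gap = a in _GAPS, b in _GAPS
        if a_gap and b_gap:
            continue
        scored += 1
        if a == b and not a_gap:
            ident += 1
    if scored == 0:
        return 0.0
    return 100.0 * ident / scored


def nj_leaf_order(labels: list[str], values: np.ndarray) -> list[str]:
    """Display order from a neighbour-joining tree on 100 - identity."""
    if len(labels) < 3:
        return sorted(labels)
    from skbio import DistanceMatrix
    from skbio.tree import nj

    order = sorted(range(len(labels)), key=lambda i: labels[i])
    dist = 100.0 - values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(dist, ids=[labels[i] for i in order])
    tree = nj(dm)
    return [tip.name for tip in tree.tips()]


def identity_matrix(msa: list[tuple[str, str]],
                    nj_order: bool = False) -> IdentityMatrix:
    """All-pairs identity matrix from an aligned FASTA record list."""
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    labels = [name for name, _ in msa]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids in MSA")
    n = len(msa)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(msa[i][1], msa[j][1])
            values[i, j] = values[j, i] = pid
    mat = IdentityMatrix(labels=labels, values=values)
    if nj_order:
        order = nj_leaf_order(labels, values)
        idx = [labels.index(l) for l in order]
        mat = IdentityMatrix(labels=order,
                             values=values[np.ix_(idx, idx)])
    return mat


def plot_identity(mat: IdentityMatrix, path: str) -> None:
    """Heatmap export of the identity matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.values, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(mat.labels)), mat.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat.labels)), mat.labels, fontsize=7)
    fig.colorbar(im, label="% identity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
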