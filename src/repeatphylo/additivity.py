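"""Deviation of allopolyploid repeat abundances from additive inheritance.

Under additive inheritance a neo-allopolyploid's repeat complement is the sum
of its two progenitors', so at equal genome coverage the expected size of
every cluster in the polyploid is the maternal count plus the paternal count.
The observed minus expected deviation, accumulated over clusters ranked from
smallest to largest expected size, traces where in the repeat landscape a
lineage gained or lost DNA after polyploidy: the curve's endpoint is the
genome-scale net repeat gain/loss and its shape separates amplifying
lineages from downsizing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import AbundanceMatrix

__all__ = [
    "ParentMap",
    "DeviationCurve",
    "expected_sizes",
    "deviation_curve",
    "curve_distance",
    "load_parent_map",
    "plot_curves",
]


@dataclass
class ParentMap:
    """polyploid species code -> (maternal code, paternal code)."""

    parents: dict[str, tuple[str, str]]

    def __post_init__(self):
        for poly, (mat, pat) in self.parents.items():
            if mat == pat:
                raise ValueError(f"{poly}: maternal and paternal parents "
                                 "must be distinct")

    def validate_against(self, taxa: list[str]) -> None:
        taxa_set = set(taxa)
        for poly, (mat, pat) in self.parents.items():
            missing = {poly, mat, pat} - taxa_set
            if missing:
                raise ValueError(f"species {sorted(missing)} not present in "
                                 "the abundance matrix")

    def __getitem__(self, poly: str) -> tuple[str, str]:
        return self.parents[poly]

    def polyploids(self) -> list[str]:
        return sorted(self.parents)


def load_parent_map(path) -> ParentMap:
    """Three-column TSV: polyploid, maternal, paternal."""
    parents = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("polyploid"):
            continue
        poly, mat, pat = line.split("\t")[:3]
        parents[poly] = (mat, pat)
    return ParentMap(parents)


def _require_raw(matrix: AbundanceMatrix) -> pd.DataFrame:
    if not isinstance(matrix, AbundanceMatrix) or getattr(matrix, "transformed", False):
        raise ValueError("additivity analysis requires a raw (untransformed) "
                         "count matrix")
    return matrix.data


def expected_sizes(matrix: AbundanceMatrix, parents: ParentMap) -> pd.DataFrame:
    """Expected cluster counts per polyploid: maternal + paternal counts."""
    df = _require_raw(matrix)
    parents.validate_against(list(df.index))
    rows = {poly: df.loc[mat] + df.loc[pat]
            for poly, (mat, pat) in parents.parents.items()}
    return pd.DataFrame(rows).T.loc[parents.polyploids()]


@dataclass
class DeviationCurve:
    """Ranked cumulative deviation from additive expectation.

    ``table`` columns: cluster_id, expected, observed, deviation,
    cumulative_deviation, cumulative_abs_deviation, rank, and the
    sign-preserving log columns used for plotting on a log scale
    (sign(c) * log10(|c| + 1)).
    """

    polyploid: str
    table: pd.DataFrame = field(repr=False)
    rank_by: str = "expected"

    @property
    def endpoint(self) -> float:
        """Net repeat gain/loss: total observed minus total expected reads."""
        return float(self.table["cumulative_deviation"].iloc[-1])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def deviation_curve(matrix: AbundanceMatrix, parents: ParentMap,
                    polyploid: str, rank_by: str = "expected") -> DeviationCurve:
    """Cumulative observed-minus-expected curve for one polyploid.

    Clusters are ranked ascending by expected size (the parental sum; this
    makes the x-axis identical across polyploids of the same parents) or by
    observed size with ``rank_by="observed"``; ties break by cluster id.
    """
    df = _require_raw(matrix)
    parents.validate_against(list(df.index))
    if polyploid not in parents.parents:
        raise KeyError(f"{polyploid!r} has no declared parents")
    mat, pat = parents[polyploid]
    expected = df.loc[mat] + df.loc[pat]
    observed = df.loc[polyploid]
    if rank_by == "expected":
        key = expected
    elif rank_by == "observed":
        key = observed
    else:
        raise ValueError("rank_by must be 'expected' or 'observed'")
    order = sorted(df.columns, key=lambda c: (key[c], c))
    tab = pd.DataFrame({
        "cluster_id": order,
        "expected": expected[order].to_numpy(),
        "observed": observed[order].to_numpy(),
    })
    tab["deviation"] = tab["observed"] - tab["expected"]
    tab["cumulative_deviation"] = tab["deviation"].cumsum()
    tab["cumulative_abs_deviation"] = tab["deviation"].abs().cumsum()
    tab["rank"] = np.arange(1, len(tab) + 1)
    c = tab["cumulative_deviation"]
    tab["log_cumulative"] = np.sign(c) * np.log10(np.abs(c) + 1.0)
    tab["log_cumulative_abs"] = np.log10(tab["cumulative_abs_deviation"] + 1.0)
    return DeviationCurve(polyploid, tab, rank_by)


def curve_distance(curves: list[DeviationCurve]) -> pd.DataFrame:
    """Pairwise L1 distance between cumulative-deviation curves on a shared
    cluster-rank grid.  Zero iff two curves are identical."""
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    ranks = [list(c.table["cluster_id"]) for c in curves]
    if any(r != ranks[0] for r in ranks[1:]):
        raise ValueError("curves are not on a shared cluster rank grid "
                         "(use rank_by='expected' with common parents)")
    names = [c.polyploid for c in curves]
    vals = np.stack([c.table["cumulative_deviation"].to_numpy() for c in curves])
    d = np.abs(vals[:, None, :] - vals[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=names, columns=names)


def plot_curves(curves: list[DeviationCurve], path) -> None:
    """Cumulative deviation vs cluster rank, sign-preserving log scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        ax.plot(c.table["rank"], c.table["log_cumulative"], label=c.polyploid)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(f"cluster rank ({curves[0].rank_by} size, ascending)")
    ax.set_ylabel("sign(c) · log10(|cumulative deviation| + 1)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
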