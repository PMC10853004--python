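"""Evolutionary conservation of replaced residues vs active-site proximity.

For each historically replaced alignment position, conservation among
descendant sequences is quantified two ways: by counting descendants that
retain the focal residue, and by Fitch parsimony (the minimum number of
state changes across the descendant phylogeny).  Either is then correlated
with the residue's distance to the bound substrate, measured externally on
a crystal structure and supplied as a table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

__all__ = [
    "ResidueSiteRecord",
    "CorrelationResult",
    "conservation_counts",
    "fitch_changes",
    "correlate",
    "read_site_records",
]

GAP_CHARS = {"-", "."}


@dataclass(frozen=True)
class ResidueSiteRecord:
    """One replaced site with structural and conservation annotations.

    Distances are in Angstroms: ``distance_closest`` from any residue atom
    to the nearest substrate atom, ``distance_ca`` from the alpha carbon to
    the substrate's carboxyl carbon (the coarser, more uniform variant).
    """

    alignment_position: int
    reference_position: int | None = None
    distance_closest: float | None = None
    distance_ca: float | None = None
    conservation_count: int | None = None
    conservation_fraction: float | None = None
    parsimony_changes: int | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    x_variable: str
    y_variable: str
    n_dropped: int = 0


def _get_alignment(alignment):
    if isinstance(alignment, (str, Path)):
        return AlignIO.read(str(alignment), "fasta")
    return alignment


def conservation_counts(
    alignment, focal_sites: Sequence[tuple[int, str]]
) -> list[tuple[int, int, float]]:
    """Count descendants retaining the focal residue at each column.

    ``focal_sites`` holds (1-based alignment column, residue) pairs.  A gap
    never counts as retained.  Returns (position, count, fraction) with
    fraction = count / number of sequences.
    """
    aln = _get_alignment(alignment)
    n_seq = len(aln)
    if n_seq == 0:
        raise ValueError("alignment is empty")
    n_col = aln.get_alignment_length()
    out = []
    for pos, residue in focal_sites:
        if not 1 <= pos <= n_col:
            raise IndexError(
                f"alignment position {pos} outside 1..{n_col}"
            )
        column = [str(rec.seq[pos - 1]).upper() for rec in aln]
        count = sum(c == residue.upper() for c in column)
        out.append((pos, count, count / n_seq))
    return out


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # a path, not newick text
        return dendropy.Tree.get(path=text, schema="newick")
    return dendropy.Tree.get(data=text, schema="newick")


def fitch_changes(tree, leaf_states: Mapping[str, str]) -> int:
    """Minimum number of state changes on the tree (Fitch parsimony).

    The classic two-pass bottom-up count: at each internal node children's
    state sets are intersected; an empty intersection takes the union and
    costs one change.  Multifurcations are folded pairwise left to right,
    which equals resolving them arbitrarily with zero-length branches.
    """
    t = _as_tree(tree)
    changes = 0
    sets: dict[int, frozenset[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            if name not in leaf_states:
                raise KeyError(f"no state supplied for leaf {name!r}")
            sets[id(node)] = frozenset({leaf_states[name]})
        else:
            acc: frozenset[str] | None = None
            for child in node.child_nodes():
                s = sets[id(child)]
                if acc is None:
                    acc = s
                elif acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    changes += 1
            sets[id(node)] = acc if acc is not None else frozenset()
    return changes


def correlate(
    records: Iterable[ResidueSiteRecord],
    x: str = "distance_closest",
    y: str = "conservation_fraction",
) -> CorrelationResult:
    """Pearson correlation between a distance and a conservation variable.

    Records missing either variable are dropped (and counted); the p-value
    is two-sided from the t transform of r.
    """
    xs, ys, dropped = [], [], 0
    for rec in records:
        xv, yv = getattr(rec, x), getattr(rec, y)
        if xv is None or yv is None or (isinstance(xv, float) and math.isnan(xv)) or (
            isinstance(yv, float) and math.isnan(yv)
        ):
            dropped += 1
            continue
        xs.append(float(xv))
        ys.append(float(yv))
    n = len(xs)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xa, ya = np.asarray(xs), np.asarray(ys)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(float(r), float(p), n, x, y, dropped)


def read_site_records(path) -> list[ResidueSiteRecord]:
    """Load a per-site record CSV (see the record fields for columns)."""
    df = pd.read_csv(path)
    if "position" not in df.columns:
        raise ValueError("site record CSV requires a 'position' column")

    def opt(row, col, cast=float):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    out = []
    for _, row in df.iterrows():
        count = opt(row, "conservation_count", int)
        n_seq = opt(row, "n_sequences", int)
        frac = None
        if count is not None and n_seq:
            frac = count / n_seq
        out.append(
            ResidueSiteRecord(
                alignment_position=int(row["position"]),
                reference_position=opt(row, "reference_position", int),
                distance_closest=opt(row, "distance_closest_A"),
                distance_ca=opt(row, "distance_ca_A"),
                conservation_count=count,
                conservation_fraction=frac,
                parsimony_changes=opt(row, "parsimony_changes", int),
            )
        )
    return out
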