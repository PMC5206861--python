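"""Hypergeometric over-representation analysis with BH FDR control.

Given a query gene set (e.g. the consensus targets of a differential miRNA),
a collection of annotation sets (pathways, GO terms) and a finite gene
universe of size N, each annotation set of size K is scored by the
upper-tail hypergeometric probability of observing at least the realized
overlap k in a draw of n = |query| genes:

    p = sum_{i >= k} C(K, i) * C(N - K, n - i) / C(N, n)

The test is one-sided (over-representation only) and p-values are converted
to q-values by the Benjamini-Hochberg step-up procedure.  GMT is the
on-disk format for annotation collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "hypergeom_enrich",
    "bh_adjust",
    "read_gmt",
]

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["set_name", "k", "K", "n", "N", "p", "q"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and an explicit universe.

    When a universe is given, every set must be contained in it.  Names are
    unique by construction (dict keys).
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            for name, members in self.sets.items():
                stray = members - self.universe
                if stray:
                    raise ValueError(
                        f"gene set {name!r} has members outside the "
                        f"universe, e.g. {sorted(stray)[:3]}")

    def __len__(self) -> int:
        return len(self.sets)

    # -- GMT I/O -----------------------------------------------------------

    def write_gmt(self, path: str | Path) -> None:
        lines = []
        for name in sorted(self.sets):
            desc = self.descriptions.get(name, "")
            members = "\t".join(sorted(self.sets[name]))
            lines.append(f"{name}\t{desc}\t{members}" if members
                         else f"{name}\t{desc}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, desc, *genes = parts
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = {g for g in genes if g}
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    Implements the classic step-up with monotonicity enforcement (cumulative
    minimum from the largest rank); q >= p elementwise and q is invariant
    under permutation of the input (up to the same permutation).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score every annotation set for over-representation in ``query``.

    Query members outside the universe are dropped (count logged); set
    members outside the universe never count toward K or k.  Returns a
    DataFrame with columns set_name, k, K, n, N, p, q sorted by p then
    set name; q is the BH adjustment over all sets in the collection.

    An empty query gives k = 0 and p = 1 everywhere; an empty universe is
    an error.
    """
    if isinstance(collection, GeneSetCollection):
        sets = collection.sets
        default_universe = collection.universe
    else:
        sets = {name: set(members) for name, members in collection.items()}
        default_universe = None
    if universe is not None:
        uni = set(universe)
    elif default_universe is not None:
        uni = set(default_universe)
    else:
        uni = set().union(*sets.values()) if sets else set()
    if not uni:
        raise ValueError("universe is empty")

    q_in = set(query)
    dropped = len(q_in - uni)
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    q_genes = q_in & uni
    N, n = len(uni), len(q_genes)

    rows = []
    for name in sorted(sets):
        members = sets[name] & uni
        K = len(members)
        k = len(members & q_genes)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    out = out.sort_values(["p", "set_name"], kind="mergesort",
                          ignore_index=True)
    return out


def write_enrichment_tsv(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)
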