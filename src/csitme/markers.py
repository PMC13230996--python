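"""Gene-set overlap utilities for annotating components against published
cell-state marker sets (Fisher exact enrichment over an explicit universe)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .states import ICSignature


@dataclass
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read marker sets from GMT or two-column (set name, gene) TSV."""
    path = Path(path)
    sets: dict[str, set] = {}
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if path.suffix.lower() == ".gmt":
        for line in lines:
            parts = line.split("\t")
            sets.setdefault(parts[0], set()).update(g for g in parts[2:] if g)
    else:
        for line in lines[1:] if "\t" in lines[0] else lines:
            name, gene = line.split("\t")[:2]
            sets.setdefault(name, set()).add(gene)
    return [GeneSet(name=k, genes=frozenset(v)) for k, v in sets.items()]


def overlap_enrichment(
    query: set | frozenset,
    reference: set | frozenset,
    universe: list | set,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Fisher exact overlap of two gene sets within a universe.

    Both sets must be subsets of the universe.  The 2x2 table is built from
    universe membership; the odds ratio is (a*d)/(b*c) and the default p is
    one-sided (enrichment).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q, r = set(query), set(reference)
    if not q <= uni:
        raise ValueError(f"query has {len(q - uni)} genes outside the universe")
    if not r <= uni:
        raise ValueError(f"reference has {len(r - uni)} genes outside the universe")
    a = len(q & r)
    b = len(q - r)
    c = len(r - q)
    d = len(uni) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(odds), float(p)


def batch_annotate(
    signatures: list[ICSignature],
    marker_sets: list[GeneSet],
    universe: list | set,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Fisher tests of every signature side against every marker set, BH per batch.

    Marker sets are intersected with the universe before testing (published
    markers routinely include genes absent from the deconvolution-confident
    space).  An empty signature side yields a row of NAs.
    """
    uni = set(universe)
    rows = []
    for sig in signatures:
        for side, genes in (("pos", sig.positive_genes), ("neg", sig.negative_genes)):
            for ms in marker_sets:
                ref = ms.genes & uni
                if not genes or not ref:
                    rows.append(
                        {"cell_type": sig.cell_type, "ic": sig.ic, "side": side,
                         "marker_set": ms.name, "odds_ratio": np.nan, "p": np.nan}
                    )
                    continue
                odds, p = overlap_enrichment(genes, ref, uni)
                rows.append(
                    {"cell_type": sig.cell_type, "ic": sig.ic, "side": side,
                     "marker_set": ms.name, "odds_ratio": odds, "p": p}
                )
    res = pd.DataFrame(rows)
    ok = res["p"].notna()
    res["fdr"] = np.nan
    if ok.any():
        res.loc[ok, "fdr"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res["significant"] = res["fdr"] < fdr
    return res
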