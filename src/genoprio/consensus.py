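"""Cross-analysis consensus: the final prioritization filter.

A gene enters the consensus table only when it is significant in every
"real" constituent analysis (each eQTL-integration run and the gene-based
GWAS test) at the chosen level. The random-phenotype negative-control p and
a user-supplied catalog membership flag are attached for reporting but never
filtered on: a genuine risk gene should be null in the negative control, and
"not documented" genes are the novel discoveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product

import pandas as pd


@dataclass
class ConsensusRow:
    gene_id: str
    pvalues: dict[str, float]  # analysis label -> p
    null_control_p: float | None
    documented: bool


def intersect_results(named_sets: dict[str, set]) -> tuple[set, dict[str, int] | None]:
    """Intersection across named gene sets plus Venn region counts (<= 4 sets).

    Venn regions are keyed by membership strings over the label order, e.g.
    ``"1011"`` = in sets 1, 3 and 4 but not 2; counts sum to |union|. With
    more than 4 sets the intersection is still computed but Venn counts are
    refused (returned as None).
    """
    if len(named_sets) < 2:
        raise ValueError("need >= 2 sets")
    labels = list(named_sets)
    sets = [set(named_sets[lbl]) for lbl in labels]
    intersection = set.intersection(*sets)
    if len(sets) > 4:
        warnings.warn("Venn counts refused for > 4 sets")
        return intersection, None
    union = set.union(*sets)
    counts: dict[str, int] = {}
    for pattern in product((0, 1), repeat=len(sets)):
        if not any(pattern):
            continue
        counts["".join(map(str, pattern))] = 0
    for g in union:
        key = "".join("1" if g in s else "0" for s in sets)
        counts[key] += 1
    return intersection, counts


def build_consensus_table(results: dict[str, dict[str, float]],
                          alpha: float = 0.05,
                          null_control: dict[str, float] | None = None,
                          catalog: set | None = None) -> list[ConsensusRow]:
    """Consensus rows: genes with p < alpha in *every* analysis in ``results``.

    ``results`` maps analysis label -> (gene -> p); the first label is the
    discovery analysis and orders the output (its p ascending). A gene absent
    from any analysis is not significant there and is excluded. The negative
    control p and catalog flag are attached without filtering.
    """
    if not results:
        raise ValueError("no analyses supplied")
    labels = list(results)
    candidates = set(results[labels[0]])
    for lbl in labels[1:]:
        candidates &= set(results[lbl])
    rows: list[ConsensusRow] = []
    missing_null: list[str] = []
    for gene in candidates:
        ps = {lbl: float(results[lbl][gene]) for lbl in labels}
        if not all(p < alpha for p in ps.values()):
            continue
        ncp = None
        if null_control is not None:
            if gene in null_control:
                ncp = float(null_control[gene])
            else:
                missing_null.append(gene)
        rows.append(ConsensusRow(gene_id=gene, pvalues=ps,
                                 null_control_p=ncp,
                                 documented=bool(catalog and gene in catalog)))
    if missing_null:
        warnings.warn(f"genes absent from the negative control: "
                      f"{sorted(missing_null)[:10]}")
    rows.sort(key=lambda r: (r.pvalues[labels[0]], r.gene_id))
    return rows


def annotate_catalog(rows: list[ConsensusRow], catalog) -> list[ConsensusRow]:
    """Set each row's documented flag from a catalog gene set."""
    cat = set(catalog)
    for r in rows:
        r.documented = r.gene_id in cat
    return rows


def rows_to_frame(rows: list[ConsensusRow]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=["gene_id", "null_control_p", "documented"])
    labels = list(rows[0].pvalues)
    data = {"gene_id": [r.gene_id for r in rows]}
    for lbl in labels:
        data[f"p_{lbl}"] = [r.pvalues[lbl] for r in rows]
    data["null_control_p"] = [r.null_control_p for r in rows]
    data["documented"] = [r.documented for r in rows]
    return pd.DataFrame(data)


def load_example_consensus():
    """Literature-reported worked example: 11 moderate-to-severe asthma genes.

    Returns (results, null_control, catalog) where ``results`` maps the four
    analysis labels (three eQTL-integration runs and the gene-based GWAS
    test) to gene -> p maps, ``null_control`` holds the random-phenotype
    negative-control p per gene, and ``catalog`` is the subset of genes
    already documented in a public GWAS catalog.
    """
    path = resources.files("genoprio.data") / "asthma_consensus_example.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    labels = ["eqtl_monocytes", "eqtl_lcl_asthma", "eqtl_lcl_ceu", "gene_based"]
    results = {lbl: dict(zip(df["gene_id"], df[lbl])) for lbl in labels}
    null_control = dict(zip(df["gene_id"], df["null_control"]))
    catalog = set(df.loc[df["documented"] == 1, "gene_id"])
    return results, null_control, catalog
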