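"""Site-to-gene mapping and flat term-overrepresentation testing.

Significant GATC sites are mapped to the gene they fall in, or to a
downstream gene whose start lies within a configurable upstream promoter
window (a site between two divergently transcribed genes may map to both).
Term membership of the mapped gene set is then tested against the annotated
universe with Fisher's exact test; following the study's convention the raw
p-values are thresholded (P < 0.1) with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

DEFAULT_UPSTREAM_WINDOW = 300
DEFAULT_ALPHA = 0.1

ANNOTATION_COLUMNS = ["gene_id", "start", "end", "strand"]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start must be <= end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Annotation table from GFF3 (gene features) or 4/5-column TSV."""
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(p)
    df = pd.read_csv(p, sep="\t")
    return [
        GeneAnnotation(
            gene_id=str(r["gene_id"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
            product=str(r.get("product", "") or ""),
        )
        for _, r in df.iterrows()
    ]


def _read_gff3(path: Path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name") or attrs.get("locus_tag")
            out.append(
                GeneAnnotation(
                    gene_id=gid,
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[6],
                    product=attrs.get("product", ""),
                )
            )
    return out


def map_sites_to_genes(
    site_positions: Iterable[int],
    annotations: Sequence[GeneAnnotation],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> tuple[set[str], pd.DataFrame, list[int]]:
    """Map duplex site positions to genes (inside span, else promoter window).

    A site inside a gene span maps to that gene; otherwise to any gene whose
    start lies within ``upstream_window`` bp downstream of the site on the
    correct strand (both genes of a divergent promoter can match).  Returns
    the mapped gene set, the site->gene pairs, and unmapped positions.
    """
    pairs = []
    unmapped = []
    for pos in sorted(set(site_positions)):
        hits = []
        for g in annotations:
            if g.start <= pos <= g.end:
                hits.append((g.gene_id, "genic"))
            elif g.strand == "+" and 0 < g.start - pos <= upstream_window:
                hits.append((g.gene_id, "upstream"))
            elif g.strand == "-" and 0 < pos - g.end <= upstream_window:
                hits.append((g.gene_id, "upstream"))
        if hits:
            for gid, rel in hits:
                pairs.append({"position": pos, "gene_id": gid, "relation": rel})
        else:
            unmapped.append(pos)
    df = pd.DataFrame(pairs, columns=["position", "gene_id", "relation"])
    return set(df["gene_id"]), df, unmapped


def fisher_exact(k: int, K: int, n: int, N: int, alternative: str = "two-sided") -> float:
    """Fisher's exact p for k of n set genes carrying a term of prevalence K/N.

    Two-sided p sums the hypergeometric probabilities of all tables (margins
    fixed) no more probable than the observed one.
    """
    if not (0 <= k <= min(K, n) and n <= N and K <= N and k >= max(0, n + K - N)):
        raise ValueError(f"inconsistent contingency counts k={k} K={K} n={n} N={N}")
    if n == 0:
        return 1.0
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def enrich_terms(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, set[str]] | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-term Fisher tests for the mapped gene set against the universe.

    Emits one row per term with at least one set member — term, k, K, n, N,
    the exact gene list tested, raw p — sorted by p and flagged significant
    at the raw threshold (no multiple-testing correction, by design).
    """
    genes = set(gene_set)
    uni = set(universe)
    stray = genes - uni
    if stray:
        raise ValueError(f"gene(s) in set but not in universe: {sorted(stray)[:5]}")
    if isinstance(term_map, pd.DataFrame):
        tm = {t: set(g["gene_id"]) for t, g in term_map.groupby("term")}
    else:
        tm = {t: set(g) for t, g in term_map.items()}

    n, N = len(genes), len(uni)
    rows = []
    for term, members in tm.items():
        members = members & uni
        k = len(members & genes)
        if k == 0:
            continue
        p = fisher_exact(k, len(members), n, N, alternative=alternative)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": len(members),
                "n": n,
                "N": N,
                "p_value": p,
                "significant": p < alpha,
                "genes": ",".join(sorted(members & genes)),
            }
        )
    return (
        pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value", "significant", "genes"])
        .sort_values(["p_value", "term"])
        .reset_index(drop=True)
    )


def load_term_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (term, gene_id) -> tidy term membership table."""
    df = pd.read_csv(path, sep="\t")
    if not {"term", "gene_id"} <= set(df.columns):
        raise ValueError("term map needs columns 'term' and 'gene_id'")
    return df


def load_reference_term_table() -> pd.DataFrame:
    """Published term -> gene membership rows for the temporally changing
    GATC-site gene set (shipped as a small TSV fixture)."""
    with resources.files("damscan.data").joinpath("reference_terms.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
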