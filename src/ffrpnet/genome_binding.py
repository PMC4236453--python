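"""Binding-site lists -> target-gene maps and binding-map comparison statistics.

A gene is a direct target of a TF when a binding site with a sufficiently
small peak p-value falls inside its promoter window (by default 250 bp
upstream to 50 bp downstream of the annotated start codon, oriented along the
gene's strand).  Binding in the promoter of an upstream operon member
propagates to all downstream genes of the operon, since the operon is
co-transcribed.  Downstream statistics compare target maps between TFs
(hypergeometric overlap, percent overlap on the smaller set) and test whether
multi-TF promoters are more common than expected for random target sets of
the same sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import hypergeom_overlap_p

DIRECT = "direct-promoter"
PROPAGATED = "operon-propagated"

GENE_COLUMNS = [
    "gene_id",
    "replicon",
    "strand",
    "start",
    "end",
    "start_codon",
    "operon_id",
    "operon_rank",
]

SITE_COLUMNS = ["tf", "replicon", "position", "intensity", "pvalue"]


@dataclass
class GenomeAnnotation:
    """Gene table plus replicon lengths.

    ``genes`` columns: gene_id, replicon, strand (+/-), start, end (1-based
    inclusive body interval), start_codon (bp coordinate of the annotated
    translation start), operon_id (or NA), operon_rank (1 = most upstream).
    """

    genes: pd.DataFrame
    replicon_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        self.genes = self.genes.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()


@dataclass(frozen=True)
class TargetMap:
    """A TF's target genes with per-target provenance."""

    tf: str
    targets: frozenset[str]
    provenance: dict[str, str] = field(hash=False, default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.targets - set(self.provenance)
        if missing:
            raise ValueError(f"provenance missing for {sorted(missing)[:3]}...")


@dataclass(frozen=True)
class OverlapResult:
    tf_a: str
    tf_b: str
    k: int
    percent_overlap: float
    pvalue: float


def promoter_window(start_codon: int, strand: str, upstream: int = 250,
                    downstream: int = 50) -> tuple[int, int]:
    """Inclusive genome-coordinate promoter window, oriented along the strand."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be nonnegative")
    if strand == "+":
        return start_codon - upstream, start_codon + downstream
    if strand == "-":
        return start_codon - downstream, start_codon + upstream
    raise ValueError(f"unknown strand {strand!r}")


def assign_targets(sites: pd.DataFrame, annotation: GenomeAnnotation,
                   p_max: float = 0.01, upstream: int = 250,
                   downstream: int = 50) -> dict[str, TargetMap]:
    """Map binding sites to target genes through promoter windows.

    Direct targets have a site with pvalue <= ``p_max`` inside their window;
    genes downstream (by operon_rank) of a direct target in the same operon
    become operon-propagated targets.  Direct provenance wins on overlap.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be nonnegative")
    genes = annotation.genes
    known = set(genes["replicon"].unique())
    bad = set(sites["replicon"].unique()) - known
    if bad:
        raise KeyError(f"binding sites on unknown replicon(s): {sorted(bad)}")

    lo = np.where(genes["strand"].values == "+",
                  genes["start_codon"].values - upstream,
                  genes["start_codon"].values - downstream)
    hi = np.where(genes["strand"].values == "+",
                  genes["start_codon"].values + downstream,
                  genes["start_codon"].values + upstream)
    gene_rep = genes["replicon"].values

    operon_members: dict[str, pd.DataFrame] = {
        str(op): grp.sort_values("operon_rank")
        for op, grp in genes.dropna(subset=["operon_id"]).groupby("operon_id")
    }

    out: dict[str, TargetMap] = {}
    passing = sites[sites["pvalue"] <= p_max]
    for tf, tf_sites in passing.groupby("tf"):
        provenance: dict[str, str] = {}
        for rep, rep_sites in tf_sites.groupby("replicon"):
            sel = gene_rep == rep
            pos = rep_sites["position"].values[:, None]
            inside = (pos >= lo[sel][None, :]) & (pos <= hi[sel][None, :])
            hit_idx = np.nonzero(inside.any(axis=0))[0]
            for gi in genes.index[sel][hit_idx]:
                provenance[genes.at[gi, "gene_id"]] = DIRECT
        # operon propagation from every direct hit
        for gid in list(provenance):
            row = genes.loc[genes["gene_id"] == gid].iloc[0]
            if pd.isna(row["operon_id"]):
                continue
            members = operon_members[str(row["operon_id"])]
            downstream_members = members.loc[
                members["operon_rank"] > row["operon_rank"], "gene_id"
            ]
            for g2 in downstream_members:
                provenance.setdefault(g2, PROPAGATED)
        out[str(tf)] = TargetMap(str(tf), frozenset(provenance), provenance)
    # TFs present in the input but with no passing site get an empty map
    for tf in sites["tf"].unique():
        out.setdefault(str(tf), TargetMap(str(tf), frozenset(), {}))
    return out


@dataclass(frozen=True)
class ContextFractions:
    site_genic: float
    site_intergenic: float
    genome_genic: float
    genome_intergenic: float


def peak_context_fractions(sites: pd.DataFrame,
                           annotation: GenomeAnnotation) -> ContextFractions:
    """Fraction of sites in gene bodies vs the genome's genic base-pair fraction."""
    genes = annotation.genes
    reps = set(sites["replicon"].unique()) | set(genes["replicon"].unique())
    missing = [r for r in reps if r not in annotation.replicon_lengths]
    if missing:
        raise KeyError(f"replicon length unknown for {sorted(missing)}")

    genic_bp = 0
    total_bp = 0
    merged: dict[str, list[tuple[int, int]]] = {}
    for rep in sorted(reps):
        total_bp += annotation.replicon_lengths[rep]
        ivs = sorted(
            zip(genes.loc[genes["replicon"] == rep, "start"],
                genes.loc[genes["replicon"] == rep, "end"])
        )
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((int(s), int(e)))
        merged[rep] = out
        genic_bp += sum(e - s + 1 for s, e in out)

    n_genic = 0
    for _, row in sites.iterrows():
        pos = row["position"]
        if any(s <= pos <= e for s, e in merged.get(row["replicon"], [])):
            n_genic += 1
    n = len(sites)
    if n == 0:
        raise ValueError("no binding sites supplied")
    sg = n_genic / n
    gg = genic_bp / total_bp
    return ContextFractions(sg, 1 - sg, gg, 1 - gg)


def target_overlap(map_a, map_b, universe) -> OverlapResult:
    """Overlap count, percent overlap (vs the smaller set) and hypergeometric p.

    p = P(X >= k) with N = |universe|, K = |A|, n = |B|.
    """
    a = set(map_a.targets) if isinstance(map_a, TargetMap) else set(map_a)
    b = set(map_b.targets) if isinstance(map_b, TargetMap) else set(map_b)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not (a <= universe and b <= universe):
        raise ValueError("target maps must be subsets of the universe")
    k = len(a & b)
    smaller = min(len(a), len(b))
    percent = 100.0 * k / smaller if smaller else 0.0
    p = hypergeom_overlap_p(k, len(universe), len(a), len(b))
    name_a = map_a.tf if isinstance(map_a, TargetMap) else "A"
    name_b = map_b.tf if isinstance(map_b, TargetMap) else "B"
    return OverlapResult(name_a, name_b, k, percent, p)


def pairwise_overlaps(target_maps: dict[str, TargetMap], universe) -> pd.DataFrame:
    """All-pairs overlap table (tf_a, tf_b, k, percent_overlap, pvalue)."""
    tfs = sorted(target_maps)
    rows = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            r = target_overlap(target_maps[a], target_maps[b], universe)
            rows.append((a, b, r.k, r.percent_overlap, r.pvalue))
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "k", "percent_overlap", "pvalue"])


def multi_binding_enrichment(target_maps: dict[str, TargetMap] | dict[str, set],
                             universe, min_tfs: int = 2, n_perm: int = 10000,
                             seed: int | None = None) -> tuple[int, float]:
    """Observed count of genes targeted by >= ``min_tfs`` TFs, with permuted p.

    The null redraws each TF's target set uniformly from the universe,
    preserving its size; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if min_tfs < 2:
        raise ValueError("min_tfs must be >= 2")
    universe = sorted(set(universe))
    n_uni = len(universe)
    index = {g: i for i, g in enumerate(universe)}
    sizes = []
    counts = np.zeros(n_uni, dtype=np.int32)
    for tf in sorted(target_maps):
        tgt = target_maps[tf]
        tgt = tgt.targets if isinstance(tgt, TargetMap) else tgt
        if len(tgt) > n_uni:
            raise ValueError(f"target set of {tf} larger than universe")
        sizes.append(len(tgt))
        for g in tgt:
            counts[index[g]] += 1
    observed = int((counts >= min_tfs).sum())

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        occ = np.zeros((m, n_uni), dtype=np.int8)
        rows = np.arange(m)[:, None]
        for size in sizes:
            if size == 0:
                continue
            u = rng.random((m, n_uni), dtype=np.float32)
            idx = np.argpartition(u, size - 1, axis=1)[:, :size]
            occ[rows, idx] += 1
        exceed += int(((occ >= min_tfs).sum(axis=1) >= observed).sum())
        done += m
    p = (1 + exceed) / (n_perm + 1)
    return observed, p


# ---------------------------------------------------------------------------
# I/O: GFF3 + operon table + peak lists
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for rep in sorted(annotation.replicon_lengths):
            fh.write(f"##sequence-region {rep} 1 {annotation.replicon_lengths[rep]}\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g['gene_id']};Name={g['gene_id']}"
            fh.write(
                f"{g['replicon']}\tffrpnet\tgene\t{int(g['start'])}\t{int(g['end'])}"
                f"\t.\t{g['strand']}\t.\t{attrs}\n"
            )


def write_operon_table(annotation: GenomeAnnotation, path) -> None:
    ops = annotation.genes.dropna(subset=["operon_id"])
    out = ops[["gene_id", "operon_id", "operon_rank"]].rename(
        columns={"operon_rank": "position_in_operon"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_annotation(gff_path, operons_path) -> GenomeAnnotation:
    """Load a GFF3 gene annotation plus the operon membership table."""
    import gffutils

    replicon_lengths: dict[str, int] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, rep, _, length = line.split()
                replicon_lengths[rep] = int(length)
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        start_codon = feat.start if feat.strand == "+" else feat.end
        rows.append((feat.id, feat.seqid, feat.strand, feat.start, feat.end,
                     start_codon, None, np.nan))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    operons = pd.read_csv(operons_path, sep="\t")
    op = operons.set_index("gene_id")
    genes["operon_id"] = genes["gene_id"].map(op["operon_id"])
    genes["operon_rank"] = genes["gene_id"].map(op["position_in_operon"])
    return GenomeAnnotation(genes, replicon_lengths)


def read_sites(path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"peak list missing columns: {missing}")
    if ((sites["pvalue"] <= 0) | (sites["pvalue"] > 1)).any():
        raise ValueError("peak p-values must lie in (0, 1]")
    if (sites["position"] < 1).any():
        raise ValueError("peak positions must be >= 1")
    return sites


def write_sites(sites: pd.DataFrame, path) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_target_maps(target_maps: dict[str, TargetMap], path) -> None:
    rows = [(tf, g, tm.provenance[g])
            for tf, tm in sorted(target_maps.items())
            for g in sorted(tm.targets)]
    pd.DataFrame(rows, columns=["tf", "gene_id", "provenance"]).to_csv(
        path, sep="\t", index=False)


def read_target_maps(path) -> dict[str, TargetMap]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for tf, grp in df.groupby("tf"):
        prov = dict(zip(grp["gene_id"], grp["provenance"]))
        out[str(tf)] = TargetMap(str(tf), frozenset(prov), prov)
    return out
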