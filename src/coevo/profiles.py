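"""Phylogenetic presence/absence profiles from homology-search hit tables.

A profile records, for one query gene, which genomes contain a homolog
(e-value at or below a threshold; the query's own genome is present by
definition).  Profiles are binary — the number of matching proteins per
genome is not used — and identical profiles are collapsed to one
distinct column whose multiplicity counts the genes it represents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "read_hits",
    "assign_ranks",
    "build_profiles",
    "deduplicate",
    "subsample_taxa",
    "flag_unexpected_hits",
]

HIT_COLUMNS = ["query", "genome", "evalue"]


@dataclass
class ProfileMatrix:
    """Binary genomes x genes matrix with per-column multiplicities.

    ``data`` holds 0/1 entries (genome rows, gene/profile columns);
    ``multiplicity`` counts, per column, how many original genes share
    that profile (1 before deduplication).
    """

    data: pd.DataFrame
    multiplicity: pd.Series = None

    def __post_init__(self):
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("profile entries must be exactly 0 or 1")
        self.data = self.data.astype(np.int8)
        if self.multiplicity is None:
            self.multiplicity = pd.Series(1, index=self.data.columns)
        self.multiplicity = self.multiplicity.reindex(self.data.columns)
        if self.multiplicity.isna().any():
            raise ValueError("multiplicity missing for some columns")

    @property
    def genomes(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def informative_genes(self) -> list[str]:
        """Columns that are neither all-present nor all-absent."""
        sums = self.data.sum(axis=0)
        n = len(self.data.index)
        return [g for g in self.data.columns if 0 < sums[g] < n]

    def to_tsv(self, path: str, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path: str) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="genome")
        df.index.name = None
        return cls(data=df)


def read_hits(path: str, genome_map: str | dict | None = None) -> pd.DataFrame:
    """Read a BLAST/rapsearch-style tabular hit file.

    Accepts either a headered TSV with at least (query, genome, evalue)
    columns, or headerless outfmt-6 (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore); in the latter case
    ``genome_map`` (TSV of subject<TAB>genome, or a dict) translates
    subject protein ids to genome ids.
    """
    head = pd.read_csv(path, sep="\t", nrows=1)
    if {"query", "evalue"} <= set(head.columns):
        hits = pd.read_csv(path, sep="\t")
    else:
        names = ["query", "subject", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
        hits = pd.read_csv(path, sep="\t", header=None, names=names)
    if "genome" not in hits.columns:
        if genome_map is None:
            raise ValueError("outfmt-6 input needs a subject->genome map")
        if isinstance(genome_map, str):
            mp = pd.read_csv(genome_map, sep="\t", header=None,
                             names=["subject", "genome"])
            genome_map = dict(zip(mp["subject"], mp["genome"]))
        hits["genome"] = hits["subject"].map(genome_map)
        if hits["genome"].isna().any():
            bad = sorted(hits.loc[hits["genome"].isna(), "subject"].unique())
            raise ValueError(f"subjects without genome mapping: {bad[:10]}")
    if (hits["evalue"] <= 0).any():
        raise ValueError("e-values must be > 0")
    return hits


def assign_ranks(hits: pd.DataFrame) -> pd.DataFrame:
    """Rank each query's matches: ascending e-value, ties by descending
    bitscore then lexical subject id.  Existing ranks are kept."""
    if "rank" in hits.columns:
        return hits
    hits = hits.copy()
    by, asc = ["query", "evalue"], [True, True]
    if "bitscore" in hits.columns:
        by, asc = by + ["bitscore"], asc + [False]
    if "subject" in hits.columns:
        by, asc = by + ["subject"], asc + [True]
    order = hits.sort_values(by, ascending=asc, kind="mergesort")
    hits.loc[order.index, "rank"] = order.groupby("query").cumcount() + 1
    hits["rank"] = hits["rank"].astype(int)
    return hits


def build_profiles(hits: pd.DataFrame, genomes: list[str], query_genome: str,
                   evalue_max: float = 1e-20,
                   inclusive: bool = True) -> ProfileMatrix:
    """Binary presence/absence matrix from a hit table.

    A gene is present in genome g when some hit has e-value <=
    ``evalue_max`` (strict < when ``inclusive=False``), and always
    present in its own ``query_genome``.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    if query_genome not in genomes:
        raise ValueError(f"query genome {query_genome!r} not in genome list")
    genomes = list(dict.fromkeys(genomes))
    unknown = set(hits["genome"]) - set(genomes)
    if unknown:
        raise ValueError(f"hits reference unknown genomes: {sorted(unknown)}")
    if hits.empty:
        warnings.warn("empty hit table: profiles contain self-presence only")
    genes = sorted(hits["query"].unique())
    data = pd.DataFrame(0, index=genomes, columns=genes, dtype=np.int8)
    op = hits["evalue"] <= evalue_max if inclusive else hits["evalue"] < evalue_max
    kept = hits.loc[op, ["query", "genome"]].drop_duplicates()
    for q, g in kept.itertuples(index=False):
        data.loc[g, q] = 1
    data.loc[query_genome, :] = 1  # a gene is present in its source genome
    return ProfileMatrix(data=data)


def deduplicate(matrix: ProfileMatrix) -> tuple[ProfileMatrix, dict]:
    """Collapse identical profile columns.

    Each distinct 0/1 vector keeps one column, named after its lexically
    smallest member gene; multiplicities are summed.  Returns the reduced
    matrix and the total gene -> distinct-profile-id mapping.
    """
    groups: dict[tuple, list[str]] = {}
    for gene in sorted(matrix.data.columns):
        key = tuple(matrix.data[gene].to_numpy())
        groups.setdefault(key, []).append(gene)
    reps = {min(members): members for members in groups.values()}
    mapping = {g: rep for rep, members in reps.items() for g in members}
    cols = sorted(reps)
    data = matrix.data[cols].copy()
    mult = pd.Series(
        {rep: int(matrix.multiplicity[members].sum())
         for rep, members in reps.items()}
    ).reindex(cols)
    return ProfileMatrix(data=data, multiplicity=mult), mapping


def subsample_taxa(matrix: ProfileMatrix, tree, n: int, keep: list[str],
                   seed: int = 0):
    """Uniform random subsample of ``n`` genomes always containing ``keep``.

    The tree is pruned to the subsample (suppressed degree-2 nodes have
    their branch lengths summed, so retained pairwise path lengths are
    unchanged).  Deterministic given ``seed``.
    """
    genomes = sorted(matrix.genomes)
    keep = sorted(set(keep))
    if not set(keep) <= set(genomes):
        raise ValueError("keep list contains genomes absent from the matrix")
    if n < len(keep):
        raise ValueError("n smaller than the keep list")
    if n > len(genomes):
        raise ValueError(f"cannot sample {n} of {len(genomes)} genomes")
    if not set(genomes) <= set(tree.tip_labels):
        raise ValueError("matrix genomes missing from the tree")
    pool = [g for g in genomes if g not in keep]
    rng = np.random.default_rng(seed)
    extra = list(rng.choice(pool, size=n - len(keep), replace=False))
    chosen = sorted(keep + extra)
    sub = ProfileMatrix(data=matrix.data.loc[chosen].copy(),
                        multiplicity=matrix.multiplicity.copy())
    return sub, tree.prune_to(chosen)


def flag_unexpected_hits(hits: pd.DataFrame, target_genomes,
                         evalue_max: float = 1e-20, rank_max: int = 20,
                         strict: bool = True) -> set:
    """Genes with a strong, high-ranking hit to any target genome.

    A gene is flagged when at least one of its hits lands in a target
    genome with e-value below ``evalue_max`` (strict <; set
    ``strict=False`` for <=) and rank at most ``rank_max`` among all of
    that gene's matches.
    """
    if rank_max < 1:
        raise ValueError("rank_max must be >= 1")
    hits = assign_ranks(hits)
    in_target = hits["genome"].isin(set(target_genomes))
    ok_e = hits["evalue"] < evalue_max if strict else hits["evalue"] <= evalue_max
    sel = hits.loc[in_target & ok_e & (hits["rank"] <= rank_max)]
    return set(sel["query"])
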