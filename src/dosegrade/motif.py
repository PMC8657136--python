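"""Canonical E-box scanning and motif-to-TSS distance statistics.

The canonical E-box CACGTG is its own reverse complement, so a forward scan
finds every genomic occurrence; + and - alignments at the same start are
collapsed to one positional record carrying a palindrome flag. An
"alignment count" mode (positions counted once per strand alignment) is kept
for comparability with aligner-derived totals.

Distances are unsigned base pairs between a gene's TSS (strand-aware 5' end,
0-based) and the motif midpoint (start + 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def _scan_one(seq: str, pattern: str) -> list[int]:
    """All (possibly overlapping) exact occurrences; case handled upstream."""
    out, pos = [], seq.find(pattern)
    while pos != -1:
        out.append(pos)
        pos = seq.find(pattern, pos + 1)
    return out


def scan_motif(genome: dict[str, str] | str, motif: str = "CACGTG"
               ) -> pd.DataFrame:
    """Exact occurrences of ``motif`` on both strands of every chromosome.

    ``genome`` is a {chrom: sequence} dict or a FASTA path. N never matches.
    Palindromic motifs yield one record per start with strand '+' and
    palindrome=True; for non-palindromic motifs, minus-strand hits record the
    0-based start of the reverse-complement match on the forward sequence.
    """
    if isinstance(genome, str):
        genome = load_fasta(genome)
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    rc = reverse_complement(motif)
    palindrome = rc == motif
    rows = []
    for chrom, seq in genome.items():
        s = seq.upper()
        for start in _scan_one(s, motif):
            rows.append((chrom, start, "+", palindrome))
        if not palindrome:
            for start in _scan_one(s, rc):
                rows.append((chrom, start, "-", False))
    hits = pd.DataFrame(rows, columns=["chrom", "start", "strand", "palindrome"])
    return hits.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def alignment_count(hits: pd.DataFrame) -> int:
    """Strand-alignment count: palindromic positions align on both strands."""
    return int(len(hits) + hits["palindrome"].sum())


def motif_midpoints(hits: pd.DataFrame, motif_length: int = 6) -> pd.DataFrame:
    out = hits.copy()
    out["midpoint"] = out["start"] + motif_length // 2
    return out


def gene_min_distance(hits: pd.DataFrame, tss: pd.DataFrame,
                      window: int = 1000) -> pd.DataFrame:
    """Per gene, the unsigned distance from the TSS to the nearest motif
    midpoint on the same chromosome, plus the <= window indicator.

    Genes on motif-free chromosomes get NaN distance and a False flag.
    ``tss`` needs columns gene_id, chrom, tss.
    """
    mids = motif_midpoints(hits).drop_duplicates(subset=["chrom", "start"])
    out = []
    for chrom, sub in tss.groupby("chrom"):
        m = np.sort(mids.loc[mids["chrom"] == chrom, "midpoint"].to_numpy())
        t = sub["tss"].to_numpy()
        if len(m) == 0:
            dist = np.full(len(t), np.nan)
        else:
            idx = np.searchsorted(m, t)
            left = np.where(idx > 0, np.abs(t - m[np.maximum(idx - 1, 0)]), np.inf)
            right = np.where(idx < len(m), np.abs(m[np.minimum(idx, len(m) - 1)] - t),
                             np.inf)
            dist = np.minimum(left, right).astype(float)
        out.append(pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(),
                                 "min_distance": dist}))
    res = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["gene_id", "min_distance"])
    res["ebox_within_1kb"] = res["min_distance"].le(window).fillna(False)
    return res.sort_values("gene_id").reset_index(drop=True)


def nearest_tss_per_motif(hits: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """For each unique motif position, the gene with the nearest TSS on its
    chromosome; ties go to the lexicographically smallest gene_id. Hits on
    chromosomes without genes are annotated unassigned (NaN gene)."""
    mids = motif_midpoints(hits).drop_duplicates(subset=["chrom", "start"])
    rows = []
    for chrom, sub in mids.groupby("chrom"):
        g = tss.loc[tss["chrom"] == chrom].sort_values(["tss", "gene_id"])
        m = sub["midpoint"].to_numpy()
        if len(g) == 0:
            rows.append(pd.DataFrame({"chrom": chrom, "start": sub["start"],
                                      "midpoint": m, "gene_id": None,
                                      "distance": np.nan}))
            continue
        t = g["tss"].to_numpy()
        ids = g["gene_id"].to_numpy()
        idx = np.searchsorted(t, m)
        li = np.maximum(idx - 1, 0)
        ri = np.minimum(idx, len(t) - 1)
        ld = np.where(idx > 0, np.abs(m - t[li]), np.inf)
        rd = np.where(idx < len(t), np.abs(t[ri] - m), np.inf)
        genes = np.empty(len(m), dtype=object)
        dist = np.minimum(ld, rd)
        for j in range(len(m)):
            if ld[j] < rd[j]:
                genes[j] = ids[li[j]]
            elif rd[j] < ld[j]:
                genes[j] = ids[ri[j]]
            else:  # equidistant: lexicographic tie-break
                genes[j] = min(ids[li[j]], ids[ri[j]])
        rows.append(pd.DataFrame({"chrom": chrom, "start": sub["start"].to_numpy(),
                                  "midpoint": m, "gene_id": genes,
                                  "distance": dist}))
    return (pd.concat(rows, ignore_index=True)
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def read_bed6(path: str) -> pd.DataFrame:
    """BED6 genes -> TSS table (strand-aware 5' end, 0-based)."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id", "score", "strand"])
    bed["tss"] = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    bed["length_bp"] = bed["end"] - bed["start"]
    return bed[["gene_id", "chrom", "tss", "strand", "length_bp"]]


def annotation_to_tss(annotation: pd.DataFrame) -> pd.DataFrame:
    """In-memory annotation (chrom/start/end/strand) -> TSS table."""
    ann = annotation.copy()
    if "tss" not in ann:
        ann["tss"] = np.where(ann["strand"] == "+", ann["start"], ann["end"] - 1)
    cols = ["gene_id", "chrom", "tss", "strand"]
    for extra in ("length_bp", "biotype"):
        if extra in ann:
            cols.append(extra)
    return ann[cols]


def write_bed6_hits(hits: pd.DataFrame, path: str, motif_length: int = 6) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(hits.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.start + motif_length}"
                     f"\tebox_{i + 1}\t0\t{row.strand}\n")
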