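"""Window intersection and gene lookup around top markers.

Intervals are 1-based and closed throughout; BED input (0-based, half-open)
is converted on read.  Candidate regions are overlaps between windows from
two evidence tracks (domestic-ancestry enrichment, PBS, XP-EHH); genes are
looked up within a +/- flank (default 100 kb) of a marker to allow for
linkage disequilibrium.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GeneRecord:
    chrom: str
    start_bp: int
    stop_bp: int
    name: str
    source_line: str = ""


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    stop_bp: int
    evidence: set
    top_marker: tuple | None = None  # (pos_bp, score)
    genes: list = field(default_factory=list)


def read_genes(path, fmt: str | None = None) -> list[GeneRecord]:
    """Read a BED (0-based half-open) or GFF3 annotation into GeneRecords."""
    path = str(path)
    if fmt is None:
        fmt = "gff3" if re.search(r"\.gff3?($|\.)", path) else "bed"
    genes: list[GeneRecord] = []
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "stop", "name"],
                         dtype={"chrom": str})
        for r in df.itertuples(index=False):
            genes.append(GeneRecord(str(r.chrom), int(r.start) + 1, int(r.stop),
                                    str(r.name)))
    elif fmt == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] not in ("gene", "mRNA", "transcript"):
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or "."
                genes.append(GeneRecord(f[0], int(f[3]), int(f[4]), name,
                                        source_line=line.strip()))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes.sort(key=lambda g: (g.chrom, g.start_bp))
    return genes


def _interval_of(w):
    if hasattr(w, "chrom"):
        return str(w.chrom), int(w.start_bp), int(w.stop_bp)
    return str(w[0]), int(w[1]), int(w[2])


def intersect_windows(set_a, set_b, evidence_a: str = "A",
                      evidence_b: str = "B") -> list[CandidateRegion]:
    """Pairwise >= 1 bp overlaps between two window lists (closed intervals).

    Each overlap becomes a CandidateRegion spanning the intersection, with
    both evidence labels recorded.  Commutative in its two inputs.
    """
    out: list[CandidateRegion] = []
    for wa in set_a:
        ca, sa, ea = _interval_of(wa)
        for wb in set_b:
            cb, sb, eb = _interval_of(wb)
            if ca == cb and sa <= eb and ea >= sb:
                out.append(CandidateRegion(chrom=ca, start_bp=max(sa, sb),
                                           stop_bp=min(ea, eb),
                                           evidence={evidence_a, evidence_b}))
    out.sort(key=lambda r: (r.chrom, r.start_bp))
    return out


def genes_near_marker(annotation: list[GeneRecord], chrom: str, pos_bp: int,
                      flank_bp: int = 100_000) -> list[GeneRecord]:
    """Genes whose span intersects [pos - flank, pos + flank] (clipped at 1)."""
    lo = max(1, pos_bp - flank_bp)
    hi = pos_bp + flank_bp
    hits = [g for g in annotation
            if g.chrom == str(chrom) and g.start_bp <= hi and g.stop_bp >= lo]
    hits.sort(key=lambda g: (g.chrom, g.start_bp))
    return hits


def candidate_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append((r.chrom, r.start_bp, r.stop_bp,
                     "+".join(sorted(r.evidence)),
                     r.top_marker[0] if r.top_marker else None,
                     ";".join(g.name for g in r.genes)))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "stop_bp",
                                       "evidence", "top_marker_bp", "genes"])
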