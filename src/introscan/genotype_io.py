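"""Genotype/haplotype dataset container and standard-format I/O.

The central object is :class:`Dataset`: a sample x variant alt-allele
dosage matrix (values 0/1/2, missing = -1), an optional phased haplotype
matrix (2*samples x variants, values 0/1), a variant table and a
sample -> population map.  Coordinates are 1-based and closed throughout;
genetic positions (cM) are interpolated from a user-supplied 3-column map
or default to a constant 1 cM/Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos_bp", "id", "ref_allele", "alt_allele", "pos_cM"]


class GenotypeIOError(ValueError):
    """Malformed input: unsorted/duplicated positions, popmap gaps, bad files."""


@dataclass
class QcConfig:
    """Site-filtering thresholds.

    ``max_missing_rate``: sites with missing-genotype rate >= this are removed
    ("at least 10%" semantics: the boundary itself is removed).
    ``min_maf``: sites with minor-allele frequency strictly below this are
    removed.  LD pruning keeps only pairs with r^2 strictly below
    ``ld_r2_max`` within a sliding window of ``ld_window_snps`` advanced by
    ``ld_step_snps``.
    """

    max_missing_rate: float = 0.10
    min_maf: float = 0.05
    ld_r2_max: float = 0.5
    ld_window_snps: int = 50
    ld_step_snps: int = 5

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class Dataset:
    """Diploid SNP dataset with optional phased haplotypes.

    ``genotypes``: (n_samples, n_variants) int8, alt-allele dosage, -1 missing.
    ``haplotypes``: (2*n_samples, n_variants) int8 or None; haplotypes 2i and
    2i+1 belong to sample i and sum to its genotype where not missing.
    """

    variants: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    popmap: dict[str, str]
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing_pop = [s for s in self.samples if s not in self.popmap]
        if missing_pop:
            raise GenotypeIOError(f"samples missing from popmap: {missing_pop[:5]}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
                raise ValueError("haplotype matrix shape mismatch")
        _check_sorted(self.variants)

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def population_of(self, sample: str) -> str:
        return self.popmap[sample]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.popmap[s] == group]

    def sample_indices(self, group: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.popmap[s] == group],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"population {group!r} not present in dataset")
        return idx

    def haplotype_indices(self, group: str) -> np.ndarray:
        idx = self.sample_indices(group)
        return np.sort(np.concatenate([2 * idx, 2 * idx + 1]))

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    # -- subsetting ----------------------------------------------------------
    def subset_variants(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )

    def subset_samples(self, keep: list[str]) -> "Dataset":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        hap_idx = np.concatenate([[2 * i, 2 * i + 1] for i in idx]) if idx.size else idx
        return replace(
            self,
            samples=list(keep),
            genotypes=self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[hap_idx],
            popmap={s: self.popmap[s] for s in keep},
        )

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))


def _check_sorted(variants: pd.DataFrame) -> None:
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
            raise GenotypeIOError(
                f"variants on {chrom} not strictly increasing at "
                f"{sub['id'].iloc[bad]} (pos {pos[bad]})"
            )
        if np.any(pos < 1):
            raise GenotypeIOError(f"non-positive position on {chrom}")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

DEFAULT_CM_PER_MB = 1.0


def read_genetic_map(path) -> pd.DataFrame:
    gmap = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "bp", "cM"], dtype={"chrom": str}
    )
    counts = gmap.groupby("chrom").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise GenotypeIOError(f"genetic map needs >=2 anchors per chromosome: {bad}")
    return gmap


def interpolate_cm(
    chroms: pd.Series, pos_bp: np.ndarray, gmap: pd.DataFrame | None
) -> np.ndarray:
    """Genetic position per variant: linear interpolation between map anchors,
    extrapolated at the terminal interval's rate; 1 cM/Mb when no map is given."""
    pos_bp = np.asarray(pos_bp, dtype=float)
    if gmap is None:
        return pos_bp / 1e6 * DEFAULT_CM_PER_MB
    out = np.empty_like(pos_bp)
    chrom_arr = np.asarray(chroms, dtype=object)
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        anchors = gmap[gmap["chrom"] == str(chrom)].sort_values("bp")
        if anchors.empty:
            out[sel] = pos_bp[sel] / 1e6 * DEFAULT_CM_PER_MB
            continue
        xb, yb = anchors["bp"].to_numpy(float), anchors["cM"].to_numpy(float)
        y = np.interp(pos_bp[sel], xb, yb)
        # np.interp clamps; re-extrapolate the tails at the terminal rates
        lo = pos_bp[sel] < xb[0]
        hi = pos_bp[sel] > xb[-1]
        r0 = (yb[1] - yb[0]) / (xb[1] - xb[0])
        r1 = (yb[-1] - yb[-2]) / (xb[-1] - xb[-2])
        y[lo] = yb[0] + (pos_bp[sel][lo] - xb[0]) * r0
        y[hi] = yb[-1] + (pos_bp[sel][hi] - xb[-1]) * r1
        out[sel] = y
    return out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict[str, str]:
    pm = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(pm["sample"], pm["population"]))


def read_dataset(path, format: str = "vcf", popmap_path=None,
                 genetic_map_path=None, popmap: dict[str, str] | None = None) -> Dataset:
    """Read a VCF or PLINK .ped/.map text pair into a :class:`Dataset`.

    ``path`` for plink_text is the shared prefix of the .ped/.map pair.
    The popmap (file or dict) must cover every sample in the file.
    """
    if popmap is None:
        if popmap_path is None:
            raise GenotypeIOError("a popmap file or mapping is required")
        popmap = read_popmap(popmap_path)
    gmap = read_genetic_map(genetic_map_path) if genetic_map_path else None
    if format == "vcf":
        variants, samples, genotypes, haplotypes = _read_vcf(path)
    elif format == "plink_text":
        variants, samples, genotypes, haplotypes = _read_plink_text(path)
    else:
        raise GenotypeIOError(f"unknown format {format!r}")
    variants["pos_cM"] = interpolate_cm(variants["chrom"], variants["pos_bp"].to_numpy(), gmap)
    return Dataset(variants=variants, samples=samples, genotypes=genotypes,
                   haplotypes=haplotypes, popmap=popmap)


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, gt_cols, hap_cols = [], [], []
    any_unphased = False
    for v in vcf:
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}",
                     v.REF, v.ALT[0] if v.ALT else "."))
        gts = v.genotype.array()  # (n, 3): allele1, allele2, phased flag
        a1, a2, ph = gts[:, 0], gts[:, 1], gts[:, 2]
        dose = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
        gt_cols.append(dose)
        if np.any((ph == 0) & (a1 >= 0)):
            any_unphased = True
        hap = np.empty(2 * len(samples), dtype=np.int8)
        hap[0::2] = np.where(a1 < 0, MISSING, a1)
        hap[1::2] = np.where(a2 < 0, MISSING, a2)
        hap_cols.append(hap)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS[:5])
    variants["chrom"] = variants["chrom"].astype(str)
    n_var = len(rows)
    genotypes = (np.stack(gt_cols, axis=1) if n_var else
                 np.empty((len(samples), 0), dtype=np.int8))
    haplotypes = None
    if n_var and not any_unphased and not np.any(genotypes == MISSING):
        haplotypes = np.stack(hap_cols, axis=1)
    return variants, samples, genotypes, haplotypes


def _read_plink_text(prefix):
    prefix = str(prefix)
    vmap = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                       names=["chrom", "id", "cM", "pos_bp"], dtype={"chrom": str})
    rows, samples = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(parts[1])
            rows.append(parts[6:])
    n_var = len(vmap)
    genotypes = np.full((len(samples), n_var), MISSING, dtype=np.int8)
    ref = np.array(["0"] * n_var, dtype=object)
    alt = np.array(["0"] * n_var, dtype=object)
    alleles = np.array(rows, dtype=object).reshape(len(samples), n_var, 2) if rows else None
    # PLINK text carries no REF designation; resolve deterministically as the
    # lexicographically smaller observed allele (round-trip identity then
    # holds whenever both alleles are observed)
    for j in range(n_var):
        col = alleles[:, j, :].ravel() if alleles is not None else np.array([])
        uniq = sorted({a for a in col if a != "0"})
        if uniq:
            ref[j] = uniq[0]
            alt[j] = uniq[1] if len(uniq) > 1 else "."
    for i in range(len(samples)):
        a = alleles[i]
        miss = (a[:, 0] == "0") | (a[:, 1] == "0")
        dose = (a[:, 0] == alt).astype(np.int8) + (a[:, 1] == alt).astype(np.int8)
        genotypes[i] = np.where(miss, MISSING, dose)
    variants = pd.DataFrame({
        "chrom": vmap["chrom"].astype(str), "pos_bp": vmap["pos_bp"].astype(int),
        "id": vmap["id"].astype(str), "ref_allele": ref, "alt_allele": alt,
    })
    return variants, samples, genotypes, None


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_dataset(ds: Dataset, path, format: str = "vcf"):
    """Write a Dataset as VCF text or a PLINK .ped/.map pair.

    VCF genotypes use the phased separator ``|`` only when haplotypes are
    present; otherwise ``/``.
    """
    if format == "vcf":
        _write_vcf(ds, path)
        return path
    if format == "plink_text":
        _write_plink_text(ds, path)
        return path
    raise GenotypeIOError(f"unknown format {format!r}")


def _write_vcf(ds: Dataset, path) -> None:
    sep = "|" if ds.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in ds.chromosomes():
            sub = ds.variants[ds.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.samples) + "\n")
        V = ds.variants
        for j in range(ds.n_variants):
            if ds.phased:
                a1 = ds.haplotypes[0::2, j]
                a2 = ds.haplotypes[1::2, j]
                gts = [f"{x}{sep}{y}" for x, y in zip(a1, a2)]
            else:
                gts = []
                for g in ds.genotypes[:, j]:
                    if g == MISSING:
                        gts.append("./.")
                    else:
                        gts.append(("0/0", "0/1", "1/1")[g])
            alt = V["alt_allele"].iloc[j]
            fh.write("\t".join([
                str(V["chrom"].iloc[j]), str(int(V["pos_bp"].iloc[j])),
                str(V["id"].iloc[j]), str(V["ref_allele"].iloc[j]),
                alt if alt not in ("", None) else ".",
                ".", "PASS", ".", "GT", *gts,
            ]) + "\n")


def _write_plink_text(ds: Dataset, prefix) -> None:
    prefix = str(prefix)
    V = ds.variants
    with open(f"{prefix}.map", "w") as fh:
        for j in range(ds.n_variants):
            fh.write(f"{V['chrom'].iloc[j]}\t{V['id'].iloc[j]}\t"
                     f"{V['pos_cM'].iloc[j]:.6f}\t{int(V['pos_bp'].iloc[j])}\n")
    ref = V["ref_allele"].to_numpy(object)
    alt = np.where(V["alt_allele"].to_numpy(object) == ".", ref,
                   V["alt_allele"].to_numpy(object))
    with open(f"{prefix}.ped", "w") as fh:
        for i, s in enumerate(ds.samples):
            fields = [ds.popmap[s], s, "0", "0", "0", "-9"]
            g = ds.genotypes[i]
            for j in range(ds.n_variants):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [ref[j], ref[j]]
                elif g[j] == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# frequencies and QC
# ---------------------------------------------------------------------------

def allele_freqs(ds: Dataset, group: str):
    """Alt-allele frequency and non-missing allele-copy count per site.

    Sites with no non-missing copies in the group get frequency NaN
    (undefined) and count 0.
    """
    idx = ds.sample_indices(group)
    g = ds.genotypes[idx].astype(float)
    miss = g == MISSING
    g[miss] = np.nan
    counts = 2 * np.sum(~miss, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freqs = np.nansum(g, axis=0) / counts
    freqs[counts == 0] = np.nan
    return freqs, counts


def haplotype_freqs(ds: Dataset, group: str):
    """Alt-allele frequency per site from the phased haplotypes of a group."""
    if not ds.phased:
        raise GenotypeIOError("dataset is not phased")
    h = ds.haplotypes[ds.haplotype_indices(group)]
    return h.mean(axis=0)


def qc_filter(ds: Dataset, cfg: QcConfig) -> Dataset:
    """Keep sites with missing rate < max_missing_rate and MAF >= min_maf.

    MAF is computed over non-missing genotypes with all samples pooled.
    Sample set and variant order are unchanged.
    """
    miss_rate = np.mean(ds.genotypes == MISSING, axis=0)
    g = ds.genotypes.astype(float)
    g[g == MISSING] = np.nan
    n_copies = 2 * np.sum(~np.isnan(g), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(g, axis=0) / n_copies
    p[n_copies == 0] = np.nan
    maf = np.minimum(p, 1 - p)
    keep = (miss_rate < cfg.max_missing_rate) & ~np.isnan(maf) & (maf >= cfg.min_maf)
    if not keep.any():
        warnings.warn("qc_filter removed every site", stacklevel=2)
    return ds.subset_variants(keep)


def _genotype_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared non-missing samples."""
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = gi[ok].astype(float), gj[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if sx == 0 and sy == 0 else 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(ds: Dataset, cfg: QcConfig) -> Dataset:
    """Windowed greedy LD pruning on genotype r^2.

    Within each window of ``ld_window_snps`` sites (advanced by
    ``ld_step_snps``), while any retained pair has r^2 >= ``ld_r2_max`` the
    later site of the worst pair is dropped.  Deterministic given input order.
    """
    n = ds.n_variants
    keep = np.ones(n, dtype=bool)
    chrom_arr = ds.variants["chrom"].to_numpy(object)
    any_missing = bool(np.any(ds.genotypes == MISSING))
    for chrom in ds.chromosomes():
        cidx = np.flatnonzero(chrom_arr == chrom)
        start = 0
        while start < len(cidx):
            widx = cidx[start:start + cfg.ld_window_snps]
            live = [j for j in widx if keep[j]]
            r2mat = None
            if not any_missing and len(live) > 1:
                g = ds.genotypes[:, live].astype(float)
                sd = g.std(axis=0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    c = np.corrcoef(g.T) ** 2
                # monomorphic pairs: r2 = 1 iff both monomorphic, else 0
                mono = sd == 0
                c[np.isnan(c)] = 0.0
                both = np.outer(mono, mono)
                c[both] = 1.0
                r2mat = c
            while True:
                worst, worst_pair = -1.0, None
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        r2 = (r2mat[a, b] if r2mat is not None else
                              _genotype_r2(ds.genotypes[:, live[a]],
                                           ds.genotypes[:, live[b]]))
                        if r2 >= cfg.ld_r2_max and r2 > worst:
                            worst, worst_pair = r2, (a, b)
                if worst_pair is None:
                    break
                keep[live[worst_pair[1]]] = False
                del live[worst_pair[1]]
                if r2mat is not None:
                    r2mat = np.delete(np.delete(r2mat, worst_pair[1], 0),
                                      worst_pair[1], 1)
            if start + cfg.ld_window_snps >= len(cidx):
                break
            start += cfg.ld_step_snps
    return ds.subset_variants(keep)
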