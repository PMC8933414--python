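"""Genotype I/O, site annotation and LD utilities.

Inbred (highly selfing) lines are modelled as haploid sequences: haploid
GT calls are kept as-is, homozygous diploid calls collapse to a single
allele and heterozygous calls become missing.  Only biallelic SNPs are
retained.  Coordinates are 1-based in VCF/GFF3 and 0-based half-open
internally and in BED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta
import gffutils

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SiteAnnotation",
    "PopulationPanel",
    "LdDecayResult",
    "read_genotypes",
    "write_genotypes",
    "read_panel",
    "annotate_degeneracy",
    "cpg_flags",
    "mask_flags_from_bed",
    "apply_site_filters",
    "ld_prune",
    "ld_r2_decay",
    "pairwise_r2",
]

MISSING = -1  # call code for missing / heterozygous-collapsed genotypes

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenotypeMatrix:
    """Haploid-coded biallelic calls for samples x sites.

    ``calls`` is an int8 array of shape (n_samples, n_sites) with values
    0 (ref), 1 (alt) or MISSING.  ``sites`` is a DataFrame with columns
    chrom, pos (1-based), ref, alt; positions are strictly increasing
    within each chromosome.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("calls shape does not match samples x sites")
        bad = ~np.isin(self.calls, [0, 1, MISSING])
        if bad.any():
            raise ValueError("calls must be 0, 1 or missing")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must increase within a chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )


@dataclass
class SiteAnnotation:
    """Per-site annotations aligned with a GenotypeMatrix's sites.

    ``degeneracy`` holds "zero-fold", "four-fold" or "other" per site
    (degeneracy is only defined inside annotated CDS; everything else,
    including 2-/3-fold positions and conflicting overlapping CDS, is
    "other").  ``L0``/``L4`` are the genome-wide counts of 0-fold and
    4-fold sites at risk, independent of which sites are polymorphic.
    """

    degeneracy: np.ndarray  # object/str array per site
    cpg_flag: np.ndarray = None
    mask_flag: np.ndarray = None
    L0: int = 0
    L4: int = 0
    categories: dict[str, np.ndarray] = field(default_factory=dict)


class PopulationPanel:
    """Mapping sample id -> population label; every sample has one label."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def from_tsv(cls, path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "population"} <= set(df.columns):
            raise ValueError("panel TSV needs sample_id and population columns")
        return cls(dict(zip(df["sample_id"], df["population"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.mapping), "population": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)

    def populations(self) -> list[str]:
        seen: list[str] = []
        for v in self.mapping.values():
            if v not in seen:
                seen.append(v)
        return seen

    def indices(self, matrix: GenotypeMatrix, pop: str) -> np.ndarray:
        if pop not in self.mapping.values():
            raise ValueError(f"unknown population label: {pop!r}")
        return np.array(
            [i for i, s in enumerate(matrix.sample_ids) if self.mapping.get(s) == pop],
            dtype=int,
        )


@dataclass
class LdDecayResult:
    """Mean r^2 in contiguous half-open distance bins."""

    bin_edges: np.ndarray  # length n_bins + 1, bp
    mean_r2: np.ndarray    # per bin, nan where no pairs
    pair_counts: np.ndarray


def read_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into a haploid-coded GenotypeMatrix.

    Haploid GTs are kept; homozygous diploid GTs collapse to one allele;
    heterozygous calls and any call to an allele other than 0/1 become
    missing.  Non-biallelic or non-SNP records are skipped with a warning.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a is not None]
            alleles = [a for a in alleles if a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) > 1:  # heterozygote -> missing
                continue
            a = alleles[0]
            if a in (0, 1):
                codes[i] = a
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(codes)
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic-SNP records")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=samples, sites=sites, calls=calls)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal GT-only VCF v4.2 (haploid GTs)."""
    code_to_gt = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rescuepop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j, row in enumerate(matrix.sites.itertuples(index=False)):
            gts = "\t".join(code_to_gt[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_panel(path) -> PopulationPanel:
    return PopulationPanel.from_tsv(path)


def _codon_degeneracy(codon: str, offset: int) -> str:
    aa = CODON_TABLE.get(codon)
    if aa is None:
        return "other"
    syn = 0
    for nt in "ACGT":
        if nt == codon[offset]:
            continue
        alt = codon[:offset] + nt + codon[offset + 1:]
        if CODON_TABLE.get(alt) == aa:
            syn += 1
    if syn == 0:
        return "zero-fold"
    if syn == 3:
        return "four-fold"
    return "other"


def annotate_degeneracy(matrix: GenotypeMatrix, gff_path, fasta_path) -> SiteAnnotation:
    """Classify sites as 0-fold / 4-fold / other from gene models.

    Walks every transcript's CDS (GFF3, via gffutils), translates the
    standard codon table, and classifies each coding genome position by
    how many of its three possible substitutions are synonymous: none ->
    zero-fold, all -> four-fold, anything else (2-/3-fold degenerate or
    non-CDS) -> other.  Positions claimed by overlapping CDS with
    conflicting classes also become "other".  Genome-wide 0-fold/4-fold
    sites-at-risk counts (L0, L4) are returned alongside the per-site
    classes for the matrix's sites.
    """
    fasta = Fasta(str(fasta_path))
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    # genome position (chrom, 0-based) -> degeneracy class
    genome: dict[tuple[str, int], str] = {}
    conflicting: set[tuple[str, int]] = set()

    parents = [f for f in db.all_features()
               if list(db.children(f, featuretype="CDS"))]
    seen_cds_parents = set()
    for parent in parents:
        if parent.id in seen_cds_parents:
            continue
        seen_cds_parents.add(parent.id)
        cds = sorted(db.children(parent, featuretype="CDS"), key=lambda c: c.start)
        strand = cds[0].strand
        # 0-based genome positions of the coding sequence, 5'->3'
        positions: list[int] = []
        for c in cds:
            positions.extend(range(c.start - 1, c.end))
        if strand == "-":
            positions = positions[::-1]
        if len(positions) % 3 != 0:
            warnings.warn(f"CDS length of {parent.id} not divisible by 3; skipped")
            continue
        chrom = cds[0].seqid
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom} absent from reference")
        seq = str(fasta[chrom][:]).upper()
        if max(positions) >= len(seq):
            raise ValueError(f"CDS of {parent.id} outside reference bounds")
        coding = "".join(seq[p] for p in positions)
        if strand == "-":
            coding = coding.translate(_COMP)
        for ci in range(0, len(positions), 3):
            codon = coding[ci:ci + 3]
            for offset in range(3):
                gpos = (chrom, positions[ci + offset])
                cls = _codon_degeneracy(codon, offset)
                prev = genome.get(gpos)
                if prev is not None and prev != cls:
                    conflicting.add(gpos)
                genome[gpos] = cls
    for gpos in conflicting:
        genome[gpos] = "other"

    L0 = sum(1 for v in genome.values() if v == "zero-fold")
    L4 = sum(1 for v in genome.values() if v == "four-fold")

    deg = np.array(
        [genome.get((row.chrom, row.pos - 1), "other")
         for row in matrix.sites.itertuples(index=False)],
        dtype=object,
    )
    return SiteAnnotation(
        degeneracy=deg,
        cpg_flag=cpg_flags(matrix, fasta_path),
        mask_flag=np.zeros(matrix.n_sites, dtype=bool),
        L0=L0,
        L4=L4,
    )


def cpg_flags(matrix: GenotypeMatrix, fasta_path) -> np.ndarray:
    """Flag sites whose reference context forms a CG dinucleotide on either strand."""
    fasta = Fasta(str(fasta_path))
    flags = np.zeros(matrix.n_sites, dtype=bool)
    seqs = {c: str(fasta[c][:]).upper() for c in matrix.sites["chrom"].unique()
            if c in fasta}
    for j, row in enumerate(matrix.sites.itertuples(index=False)):
        seq = seqs.get(row.chrom)
        if seq is None:
            continue
        i = row.pos - 1
        if seq[i:i + 2] == "CG" or (i > 0 and seq[i - 1:i + 1] == "CG"):
            flags[j] = True
    return flags


def mask_flags_from_bed(matrix: GenotypeMatrix, bed_path) -> np.ndarray:
    """Flag matrix sites falling in BED intervals (0-based half-open)."""
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={"chrom": str})
    flags = np.zeros(matrix.n_sites, dtype=bool)
    for chrom, grp in bed.groupby("chrom"):
        in_chrom = matrix.sites["chrom"] == chrom
        if not in_chrom.any():
            continue
        pos0 = matrix.sites.loc[in_chrom, "pos"].to_numpy() - 1
        hit = np.zeros(pos0.size, dtype=bool)
        for start, end in zip(grp["start"], grp["end"]):
            hit |= (pos0 >= start) & (pos0 < end)
        flags[np.flatnonzero(in_chrom.to_numpy())] = hit
    return flags


def apply_site_filters(matrix: GenotypeMatrix, annotations: SiteAnnotation | None = None,
                       max_missing: float = 0.05, drop_cpg: bool = False,
                       drop_masked: bool = False):
    """Drop sites with too much missing data and optionally CpG/masked sites.

    Retains sites whose missing fraction is <= max_missing (the published
    rule removes sites with *more than* 5% missing).  Returns the filtered
    matrix, the kept site indices and per-criterion removal counts.
    """
    miss_frac = (matrix.calls == MISSING).mean(axis=0)
    keep = miss_frac <= max_missing
    removed = {"missing": int((~keep).sum()), "cpg": 0, "masked": 0}
    if drop_cpg:
        if annotations is None or annotations.cpg_flag is None:
            raise ValueError("drop_cpg requires annotations with cpg_flag")
        hit = keep & annotations.cpg_flag
        removed["cpg"] = int(hit.sum())
        keep &= ~annotations.cpg_flag
    if drop_masked:
        if annotations is None or annotations.mask_flag is None:
            raise ValueError("drop_masked requires annotations with mask_flag")
        hit = keep & annotations.mask_flag
        removed["masked"] = int(hit.sum())
        keep &= ~annotations.mask_flag
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("all sites removed by filters")
    return matrix.take_sites(idx), idx, removed


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared allele-indicator correlation over samples complete for both sites."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok].astype(float), b[ok].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(matrix: GenotypeMatrix, window: int = 50, step: int = 10,
             r2_threshold: float = 0.1) -> np.ndarray:
    """Greedy windowed LD pruning (indep-pairwise style); returns kept site indices.

    Within each sliding window, while any kept pair exceeds the r^2
    threshold, the pair member with greater missingness is removed (ties
    broken by removing the later position).  Deterministic.
    """
    if matrix.n_sites < 2:
        raise ValueError("need at least two sites")
    if window < step:
        raise ValueError("window must be >= step")
    n_sites = matrix.n_sites
    missingness = (matrix.calls == MISSING).mean(axis=0)
    keep = np.ones(n_sites, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, n_sites)
        idx = [i for i in range(start, stop) if keep[i]]
        changed = True
        while changed:
            changed = False
            for ii in range(len(idx)):
                i = idx[ii]
                if not keep[i]:
                    continue
                for jj in range(ii + 1, len(idx)):
                    j = idx[jj]
                    if not keep[j]:
                        continue
                    r2 = pairwise_r2(matrix.calls[:, i], matrix.calls[:, j])
                    if np.isnan(r2) or r2 <= r2_threshold:
                        continue
                    if missingness[i] > missingness[j]:
                        keep[i] = False
                    else:
                        keep[j] = False  # equal missingness: drop later position
                    changed = True
                    break
                if changed:
                    break
            idx = [i for i in idx if keep[i]]
        if stop == n_sites:
            break
        start += step
    return np.flatnonzero(keep)


def ld_r2_decay(matrix: GenotypeMatrix, max_distance: int = 10_000,
                bin_width: int = 1_000) -> LdDecayResult:
    """Mean pairwise r^2 by distance bin, up to max_distance.

    Pairs are restricted to the same chromosome, binned into half-open
    distance intervals of ``bin_width`` bp, and r^2 values averaged per
    bin.  Pairs at exactly max_distance or beyond are excluded.
    """
    n_bins = max_distance // bin_width
    edges = np.arange(0, max_distance + bin_width, bin_width)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    for chrom in np.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        for a_i in range(idx.size):
            i = idx[a_i]
            for b_i in range(a_i + 1, idx.size):
                j = idx[b_i]
                d = int(pos_arr[j] - pos_arr[i])
                if d >= max_distance:
                    break
                r2 = pairwise_r2(matrix.calls[:, i], matrix.calls[:, j])
                if np.isnan(r2):
                    continue
                b = d // bin_width
                sums[b] += r2
                counts[b] += 1
    if counts.sum() == 0:
        warnings.warn("no eligible SNP pairs for LD decay")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayResult(bin_edges=edges, mean_r2=mean_r2, pair_counts=counts)
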