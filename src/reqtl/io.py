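"""Readers and writers for the formats the package consumes.

Conventions
-----------
* Gene annotations come from BED (0-based, half-open); SNP positions from
  VCF (1-based).  Internally every position is 0-based.
* Genotype dosages count copies of the **minor** allele, the orientation
  being determined over all non-missing individuals at load time (ties at
  frequency 0.5 keep the alt-allele orientation).
* Expression tables are pandas DataFrames indexed by gene id with a
  two-level column index ``(individual, condition)`` where condition is
  ``"treated"`` or ``"control"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("treated", "control")
MISSING_TOKENS = {".", "NA", "nan", ""}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, dialect: str = "wide") -> pd.DataFrame:
    """Read a paired expression table.

    ``dialect="wide"``: one row per gene; first column ``gene_id``; data
    columns named ``<individual>:<condition>``.  ``dialect="long"``: columns
    ``gene_id, individual, condition, value``.

    Every individual must appear in both conditions; an individual present
    in only one is a hard error naming the individual.
    """
    if dialect == "wide":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        pairs = []
        for col in df.columns:
            ind, _, cond = col.rpartition(":")
            if not ind or cond not in CONDITIONS:
                raise ValueError(
                    f"column {col!r} is not of the form '<individual>:<condition>'"
                )
            pairs.append((ind, cond))
        df.columns = pd.MultiIndex.from_tuples(pairs, names=["individual", "condition"])
    elif dialect == "long":
        long = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"gene_id", "individual", "condition", "value"}
        if not required.issubset(long.columns):
            raise ValueError(f"long dialect requires columns {sorted(required)}")
        bad = set(long["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        df = long.pivot_table(
            index="gene_id", columns=["individual", "condition"], values="value"
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    _check_paired_columns(df)
    if not np.issubdtype(np.asarray(df.to_numpy()).dtype, np.number):
        values = df.to_numpy(dtype=object)
        bad = np.argwhere(
            ~np.vectorize(lambda v: isinstance(v, (int, float, np.number)))(values)
        )
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if df.isna().any().any():
        na = df.isna()
        gene = df.index[na.any(axis=1)][0]
        col = df.columns[na.loc[gene]][0]
        raise ValueError(f"missing value at gene {gene!r}, column {col!r}")
    return df.sort_index(axis=1)


def _check_paired_columns(df: pd.DataFrame) -> None:
    inds = df.columns.get_level_values("individual")
    missing = []
    for ind in pd.unique(inds):
        have = set(df[ind].columns)
        if have != set(CONDITIONS):
            missing.append((ind, sorted(set(CONDITIONS) - have)))
    if missing:
        msg = "; ".join(f"{ind} lacks {conds}" for ind, conds in missing)
        raise ValueError(f"individuals missing a condition: {msg}")


def write_expression(df: pd.DataFrame, path: str | Path, dialect: str = "wide") -> None:
    """Write a paired expression table read by :func:`read_expression`."""
    if dialect == "wide":
        flat = df.copy()
        flat.columns = [f"{ind}:{cond}" for ind, cond in df.columns]
        flat.index.name = "gene_id"
        flat.to_csv(path, sep="\t", float_format="%.17g")
    elif dialect == "long":
        long = df.stack(list(range(df.columns.nlevels)), future_stack=True)
        long.name = "value"
        long = long.reset_index()
        long.columns = ["gene_id", "individual", "condition", "value"]
        long.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def expression_individuals(df: pd.DataFrame) -> list[str]:
    return list(pd.unique(df.columns.get_level_values("individual")))


# ---------------------------------------------------------------------------
# gene annotations (BED)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene annotations from BED (3+ columns; name in column 4).

    Returns a DataFrame indexed by gene id with columns chrom, start, end,
    strand (0-based half-open coordinates, as in the file).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((name, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    return df.set_index("gene_id")


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, row in genes.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{gene_id}\t0\t"
                f"{row.get('strand', '.')}\n"
            )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """SNP × individual minor-allele dosage matrix.

    ``dosages`` is float with NaN for missing; ``pos`` is 1-based (VCF
    convention, ``pos0`` gives the 0-based position).  ``flipped`` records
    SNPs whose dosages were re-oriented from alt to ref at load time.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    individuals: list[str]
    populations: np.ndarray | None = None
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flipped is None:
            self.flipped = np.zeros(len(self.snp_ids), dtype=bool)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids are not unique")
        if self.dosages.shape != (len(self.snp_ids), len(self.individuals)):
            raise ValueError("dosage matrix shape mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def pos0(self) -> np.ndarray:
        """0-based SNP positions."""
        return self.pos - 1

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing individuals."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=1) / 2.0

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        pops = self.populations[idx] if self.populations is not None else None
        return GenotypeMatrix(
            self.snp_ids, self.chrom, self.pos, self.ref, self.alt,
            self.dosages[:, idx], list(ids), pops, self.flipped.copy(),
        )


def orient_to_minor_allele(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip alt-allele dosages so each SNP counts its minor allele.

    Frequency is computed over non-missing individuals; an exact tie at
    0.5 keeps the alt orientation.  Returns (dosages, flipped mask).
    """
    dosages = dosages.astype(float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=1) / 2.0
    flip = freq > 0.5
    dosages[flip] = 2.0 - dosages[flip]
    return dosages, flip


def read_genotypes(
    path: str | Path,
    format: str | None = None,
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT-based, biallelic) or a dosage TSV.

    Multi-allelic VCF records are skipped with a logged warning.  Dosages
    are re-oriented to count the minor allele.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage_tsv"
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "dosage_tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if populations is not None:
        gm.populations = np.array([populations.get(i, "NA") for i in gm.individuals])
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s at %s:%d", var.ID, var.CHROM, var.POS
            )
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    dosages = np.array(rows) if rows else np.empty((0, len(individuals)))
    dosages, flipped = orient_to_minor_allele(dosages)
    return GenotypeMatrix(
        np.array(snp_ids), np.array(chroms), np.array(poss, dtype=int),
        np.array(refs), np.array(alts), dosages, individuals, None, flipped,
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=sorted(MISSING_TOKENS))
    meta = ["snp_id", "chrom", "pos", "ref", "alt"]
    if not set(meta).issubset(df.columns):
        raise ValueError(f"dosage TSV requires columns {meta}")
    individuals = [c for c in df.columns if c not in meta]
    dosages = df[individuals].to_numpy(dtype=float)
    valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not valid.all():
        s, i = np.argwhere(~valid)[0]
        raise ValueError(
            f"dosage out of {{0,1,2,missing}} at SNP {df['snp_id'].iloc[s]!r},"
            f" individual {individuals[i]!r}"
        )
    dosages, flipped = orient_to_minor_allele(dosages)
    return GenotypeMatrix(
        df["snp_id"].to_numpy(str), df["chrom"].to_numpy(str),
        df["pos"].to_numpy(int), df["ref"].to_numpy(str), df["alt"].to_numpy(str),
        dosages, individuals, None, flipped,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields from a dosage matrix."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals) + "\n"
        )
        for s in range(gm.n_snps):
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[d] for d in gm.dosages[s]
            )
            fh.write(
                f"{gm.chrom[s]}\t{gm.pos[s]}\t{gm.snp_ids[s]}\t{gm.ref[s]}\t"
                f"{gm.alt[s]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# cis-window mapping
# ---------------------------------------------------------------------------

def map_cis_snps(
    genes: pd.DataFrame, gm: GenotypeMatrix, window: int
) -> dict[str, np.ndarray]:
    """Assign SNPs to genes within ``window`` bp of the gene body.

    SNP *s* belongs to gene *g* iff they share a chromosome and the SNP's
    0-based position lies in the half-open interval
    ``[g.start - window, g.end + window)``; strand is ignored.  Returns
    gene id → array of SNP row indices (sorted by position).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pos0 = gm.pos0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == chrom)
        order = idx[np.argsort(pos0[idx], kind="stable")]
        by_chrom[chrom] = (pos0[order], order)
    out: dict[str, np.ndarray] = {}
    for gene_id, row in genes.iterrows():
        entry = by_chrom.get(row.chrom)
        if entry is None:
            out[gene_id] = np.empty(0, dtype=int)
            continue
        sorted_pos, order = entry
        lo = np.searchsorted(sorted_pos, row.start - window, side="left")
        hi = np.searchsorted(sorted_pos, row.end + window, side="left")
        out[gene_id] = order[lo:hi]
    return out
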