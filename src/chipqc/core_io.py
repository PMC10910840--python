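"""Domain containers and text-format I/O shared by every pipeline stage.

Genotypes are stored as alt-allele dosage: ``0`` hom-ref, ``1`` het,
``2`` hom-alt, with :data:`MISSING` (``-1``) as a dedicated sentinel.
Coordinates are 1-based and fully closed (VCF convention); genotypes are
unphased and any phase separators in input are collapsed.  Half-called
genotypes (one allele missing) are mapped to MISSING.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chipqc")

#: sentinel for a missing genotype call; never a valid dosage
MISSING: int = -1

#: functional-annotation vocabulary used throughout
CATEGORIES = (
    "intron",
    "intergenic",
    "synonymous",
    "non_synonymous",
    "utr5",
    "utr3",
    "unknown",
)

VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "category")


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


class ChipQCError(Exception):
    """Base class for package errors."""


class ParseError(ChipQCError):
    """Raised when an input file cannot be parsed under the named dialect."""


class UnsupportedRecordError(ChipQCError):
    """Raised for records outside the supported subset (e.g. ploidy != 2)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Samples x biallelic SNPs with per-variant and per-sample metadata.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample labels.
    variants
        One row per SNP with columns ``id, chrom, pos, ref, alt, category``
        (``pos`` 1-based bp; ``category`` drawn from :data:`CATEGORIES`).
        Extra columns (e.g. a probe-performance score) are carried along.
    calls
        ``(n_samples, n_snps)`` int8 matrix of alt-allele dosages with
        :data:`MISSING` for no-calls.
    sample_meta
        Optional frame indexed by sample id with ``population`` and decimal
        ``lat`` / ``lon`` columns.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ChipQCError("calls must be a 2-D samples x SNPs matrix")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ChipQCError("sample ids must be unique")
        ns, nv = self.calls.shape
        if ns != len(self.sample_ids):
            raise ChipQCError(
                f"{len(self.sample_ids)} sample ids but {ns} call rows"
            )
        if nv != len(self.variants):
            raise ChipQCError(
                f"{len(self.variants)} variants but {nv} call columns"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ChipQCError("calls contain codes outside {0,1,2,MISSING}")
        self.variants = self.variants.reset_index(drop=True)
        if nv:
            if (self.variants["pos"] <= 0).any():
                raise ChipQCError("positions must be positive (1-based)")
            if (self.variants["ref"] == self.variants["alt"]).any():
                raise ChipQCError("ref and alt alleles must differ")

    # -- shape -------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    # -- derived per-locus / per-sample statistics -------------------------
    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing calls (nan if none)."""
        called = self.called_mask()
        n = called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missingness(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return (self.calls == MISSING).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def het_fraction(self) -> np.ndarray:
        """Per-sample heterozygous fraction over non-missing calls."""
        called = self.called_mask()
        n = called.sum(axis=1)
        het = (self.calls == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of samples with a call."""
        return 1.0 - self.snp_missingness()

    def populations(self) -> pd.Series:
        if self.sample_meta is None or "population" not in self.sample_meta:
            raise ChipQCError("population labels required but absent")
        return self.sample_meta.loc[self.sample_ids, "population"]

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        samples: Sequence[str] | np.ndarray | None = None,
        snps: Sequence[str] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given sample/SNP ids
        (or boolean masks), preserving order of the masks' own axes."""
        s_idx = np.arange(self.n_samples)
        v_idx = np.arange(self.n_snps)
        if samples is not None:
            samples = np.asarray(samples)
            if samples.dtype == bool:
                s_idx = np.flatnonzero(samples)
            else:
                lookup = {s: i for i, s in enumerate(self.sample_ids)}
                s_idx = np.array([lookup[s] for s in samples], dtype=int)
        if snps is not None:
            snps = np.asarray(snps)
            if snps.dtype == bool:
                v_idx = np.flatnonzero(snps)
            else:
                lookup = {v: i for i, v in enumerate(self.variants["id"])}
                v_idx = np.array([lookup[v] for v in snps], dtype=int)
        meta = self.sample_meta
        ids = [self.sample_ids[i] for i in s_idx]
        if meta is not None:
            meta = meta.loc[[s for s in ids if s in meta.index]]
        return GenotypeDataset(
            sample_ids=ids,
            variants=self.variants.iloc[v_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(s_idx, v_idx)].copy(),
            sample_meta=meta,
        )


@dataclass
class PlatformCallSet:
    """A :class:`GenotypeDataset` tagged with platform identity and per-call
    quality: read depth for sequencing, FLD and per-SNP call rate for arrays.
    """

    base: GenotypeDataset
    platform: str  # "array" | "sequencing"
    depth: np.ndarray | None = None  # (n_samples, n_snps) read counts
    fld: np.ndarray | None = None  # per-SNP Fisher linear discriminant
    snp_call_rate: np.ndarray | None = None  # per-SNP, defaults to realized

    def __post_init__(self) -> None:
        if self.platform not in ("array", "sequencing"):
            raise ChipQCError(f"unknown platform {self.platform!r}")
        if (self.depth is not None) != (self.platform == "sequencing"):
            raise ChipQCError("depth present iff platform == sequencing")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.base.calls.shape:
                raise ChipQCError("depth shape must match calls")
            if (self.depth < 0).any():
                raise ChipQCError("depths must be non-negative")
        if self.fld is not None:
            self.fld = np.asarray(self.fld, dtype=float)
            if not np.isfinite(self.fld).all():
                raise ChipQCError("FLD must be finite where present")
        if self.snp_call_rate is None:
            self.snp_call_rate = self.base.call_rate()
        else:
            self.snp_call_rate = np.asarray(self.snp_call_rate, dtype=float)
            if ((self.snp_call_rate < 0) | (self.snp_call_rate > 1)).any():
                raise ChipQCError("call rates must lie in [0, 1]")

    @property
    def calls(self) -> np.ndarray:
        return self.base.calls

    def subset_snps(self, snps) -> "PlatformCallSet":
        snps = np.asarray(snps)
        if snps.dtype == bool:
            v_idx = np.flatnonzero(snps)
        else:
            lookup = {v: i for i, v in enumerate(self.base.variants["id"])}
            v_idx = np.array([lookup[v] for v in snps], dtype=int)
        return PlatformCallSet(
            base=self.base.subset(snps=snps),
            platform=self.platform,
            depth=None if self.depth is None else self.depth[:, v_idx].copy(),
            fld=None if self.fld is None else self.fld[v_idx].copy(),
            snp_call_rate=self.snp_call_rate[v_idx].copy(),
        )


@dataclass
class ScaffoldOrder:
    """Ordered scaffold layout used to build a chromosome-scale coordinate."""

    scaffolds: list[tuple[str, int, str]]  # (scaffold_id, length_bp, chrom_id)

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise ChipQCError("each scaffold may appear only once")
        if any(length <= 0 for _, length, _ in self.scaffolds):
            raise ChipQCError("scaffold lengths must be positive")


# ---------------------------------------------------------------------------
# genotype file formats
# ---------------------------------------------------------------------------

_FORMATS = ("vcf", "plink_text", "tsv")


def read_genotypes(path: str, format: str = "vcf", platform: str | None = None) -> PlatformCallSet:
    """Read a biallelic genotype call set.

    Multiallelic / non-SNP records are skipped (a count is logged); ploidy
    other than 2 raises :class:`UnsupportedRecordError`.  ``platform``
    defaults to ``sequencing`` when per-call depth is present, else ``array``.
    """
    if format not in _FORMATS:
        raise ChipQCError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "vcf":
        ds, depth = _read_vcf(path)
    elif format == "plink_text":
        ds, depth = _read_plink_text(path), None
    else:
        ds, depth = _read_tsv(path), None
    if platform is None:
        platform = "sequencing" if depth is not None else "array"
    if platform == "sequencing" and depth is None:
        depth = np.zeros_like(ds.calls, dtype=np.int32)
    if platform == "array":
        depth = None
    return PlatformCallSet(base=ds, platform=platform, depth=depth)


def write_genotypes(dataset: GenotypeDataset | PlatformCallSet, path: str, format: str = "vcf") -> str:
    """Write a call set so that :func:`read_genotypes` round-trips calls,
    sample/variant ids and alleles exactly.  Returns the path written."""
    if isinstance(dataset, PlatformCallSet):
        base, depth = dataset.base, dataset.depth
    else:
        base, depth = dataset, None
    if format == "vcf":
        _write_vcf(base, depth, path)
    elif format == "plink_text":
        _write_plink_text(base, path)
    elif format == "tsv":
        _write_tsv(base, path)
    else:
        raise ChipQCError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return path


# -- VCF --------------------------------------------------------------------


def _read_vcf(path: str) -> tuple[GenotypeDataset, np.ndarray | None]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ChipQCError("cyvcf2 is required for VCF input") from exc
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        vcf = VCF(path)
        samples = list(vcf.samples)
    except Exception as exc:
        raise ParseError(f"malformed VCF header in {path}: {exc}") from exc

    rows, call_cols, depth_cols = [], [], []
    skipped = 0
    any_depth = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        geno = var.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(geno):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise UnsupportedRecordError(
                    f"{path}: ploidy {len(alleles)} at {var.CHROM}:{var.POS} unsupported"
                )
            a0, a1 = alleles
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        call_cols.append(col)
        try:
            dp = var.format("DP")
        except KeyError:  # DP not declared in the header
            dp = None
        if dp is not None:
            any_depth = True
            d = np.asarray(dp).reshape(-1).astype(np.int64)
            d[d < 0] = 0
            depth_cols.append(d)
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int64))
        category = var.INFO.get("CATEGORY") or "unknown"
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0], category))
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    calls = (np.column_stack(call_cols) if call_cols
             else np.empty((len(samples), 0), dtype=np.int8))
    depth = np.column_stack(depth_cols).astype(np.int32) if (depth_cols and any_depth) else None
    ds = GenotypeDataset(sample_ids=samples, variants=variants, calls=calls)
    return ds, depth


def _write_vcf(ds: GenotypeDataset, depth: np.ndarray | None, path: str) -> None:
    fmt = "GT:DP" if depth is not None else "GT"
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(ds.variants["chrom"]) if ds.n_snps else []:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=CATEGORY,Number=1,Type=String,'
                 'Description="Functional annotation category">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        for j, row in ds.variants.iterrows():
            cells = []
            for i in range(ds.n_samples):
                cell = gt_map[int(ds.calls[i, j])]
                if depth is not None:
                    cell += f":{int(depth[i, j])}"
                cells.append(cell)
            info = f"CATEGORY={row['category']}"
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t{info}\t{fmt}\t" + "\t".join(cells) + "\n")


# -- PLINK-style text -------------------------------------------------------
#
# One sample per .ped row: FID IID PAT MAT SEX PHENO then one allele pair per
# SNP ("0 0" = missing).  The .map carries chrom/id/cM/pos.  Because .ped/.map
# do not record allele polarity, a .ref sidecar (id, ref, alt, category) is
# written and consumed when present; otherwise ref defaults to the major
# allele (ties broken lexicographically).


def _plink_prefix(path: str) -> str:
    for ext in (".ped", ".map", ".ref"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


def _write_plink_text(ds: GenotypeDataset, path: str) -> None:
    prefix = _plink_prefix(path)
    with open(prefix + ".map", "w") as fh:
        for _, row in ds.variants.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    ref = ds.variants["ref"].to_numpy()
    alt = ds.variants["alt"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(ds.n_snps):
                g = ds.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref[j], ref[j]]
                elif g == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(fields) + "\n")
    with open(prefix + ".ref", "w") as fh:
        fh.write("id\tref\talt\tcategory\n")
        for _, row in ds.variants.iterrows():
            fh.write(f"{row['id']}\t{row['ref']}\t{row['alt']}\t{row['category']}\n")


def _read_plink_text(path: str) -> GenotypeDataset:
    prefix = _plink_prefix(path)
    if not os.path.exists(prefix + ".ped") or not os.path.exists(prefix + ".map"):
        raise ParseError(f"need {prefix}.ped and {prefix}.map")
    mapdf = pd.read_csv(
        prefix + ".map", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str},
    )
    n_snps = len(mapdf)
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), n_snps, 2) \
        if sample_ids else np.empty((0, n_snps, 2), dtype=object)

    if os.path.exists(prefix + ".ref"):
        refdf = pd.read_csv(prefix + ".ref", sep="\t", dtype=str).set_index("id")
        ref = refdf.loc[mapdf["id"], "ref"].to_numpy()
        alt = refdf.loc[mapdf["id"], "alt"].to_numpy()
        category = (refdf.loc[mapdf["id"], "category"].to_numpy()
                    if "category" in refdf else np.full(n_snps, "unknown"))
    else:
        ref = np.empty(n_snps, dtype=object)
        alt = np.empty(n_snps, dtype=object)
        category = np.full(n_snps, "unknown", dtype=object)
        for j in range(n_snps):
            col = alleles[:, j, :].reshape(-1)
            col = col[col != "0"]
            uniq, counts = np.unique(col, return_counts=True)
            if len(uniq) == 0:
                ref[j], alt[j] = "N", "A"
            elif len(uniq) == 1:
                ref[j], alt[j] = uniq[0], ("A" if uniq[0] != "A" else "C")
            elif len(uniq) == 2:
                order = np.lexsort((uniq, -counts))
                ref[j], alt[j] = uniq[order[0]], uniq[order[1]]
            else:
                raise UnsupportedRecordError(
                    f"{prefix}.ped: SNP {mapdf['id'][j]} has >2 alleles"
                )

    calls = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    for i in range(len(sample_ids)):
        for j in range(n_snps):
            a, b = alleles[i, j]
            if a == "0" or b == "0":
                continue  # half-calls and no-calls -> MISSING
            dose = int(a == alt[j]) + int(b == alt[j])
            if (a not in (ref[j], alt[j])) or (b not in (ref[j], alt[j])):
                raise UnsupportedRecordError(
                    f"{prefix}.ped: allele outside {{ref,alt}} at SNP {mapdf['id'][j]}"
                )
            calls[i, j] = dose
    variants = pd.DataFrame({
        "id": mapdf["id"], "chrom": mapdf["chrom"], "pos": mapdf["pos"],
        "ref": ref, "alt": alt, "category": category,
    })
    return GenotypeDataset(sample_ids=sample_ids, variants=variants, calls=calls)


# -- TSV matrix -------------------------------------------------------------


def _write_tsv(ds: GenotypeDataset, path: str) -> None:
    df = ds.variants[list(VARIANT_COLUMNS)].copy()
    for i, sid in enumerate(ds.sample_ids):
        col = ds.calls[i, :].astype(object)
        col[ds.calls[i, :] == MISSING] = "NA"
        df[sid] = col
    df.to_csv(path, sep="\t", index=False)


def _read_tsv(path: str) -> GenotypeDataset:
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    sample_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    calls = np.full((len(sample_ids), len(df)), MISSING, dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        col = df[sid].to_numpy()
        ok = ~pd.isna(col) & (col != "NA")
        calls[i, ok] = np.asarray(col[ok], dtype=float).astype(np.int8)
    variants = df[list(VARIANT_COLUMNS)].copy()
    return GenotypeDataset(sample_ids=sample_ids, variants=variants, calls=calls)


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------


def read_annotation_table(path: str) -> pd.DataFrame:
    """TSV of ``id<TAB>category`` assigning each SNP a functional category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "category"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns id, category")
    return df


def read_pedigree(path: str) -> pd.DataFrame:
    """TSV with columns ``family_id, parent1, parent2`` then offspring ids.

    Returns a frame with one row per family and an ``offspring`` list column.
    """
    fams = []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["family_id", "parent1", "parent2"]:
            raise ParseError(f"{path}: expected header family_id parent1 parent2 ...")
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            fams.append((fields[0], fields[1], fields[2], fields[3:]))
    return pd.DataFrame(fams, columns=["family_id", "parent1", "parent2", "offspring"])


def write_pedigree(families: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tparent1\tparent2\toffspring\n")
        for _, row in families.iterrows():
            fh.write("\t".join([row["family_id"], row["parent1"], row["parent2"],
                                *row["offspring"]]) + "\n")


def read_sample_metadata(path: str) -> pd.DataFrame:
    """TSV with ``sample_id, population`` and optional ``lat, lon`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: expected a sample_id column")
    return df.set_index("sample_id")


def write_sample_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_scaffold_order(path: str) -> ScaffoldOrder:
    """TSV with columns ``scaffold_id, length_bp, chromosome_id`` in assembly order."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "chromosome_id": str})
    need = {"scaffold_id", "length_bp", "chromosome_id"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(need)}")
    return ScaffoldOrder(
        scaffolds=[(r.scaffold_id, int(r.length_bp), r.chromosome_id)
                   for r in df.itertuples()]
    )
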