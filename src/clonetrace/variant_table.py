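"""Somatic variant tables with per-timepoint read counts.

A variant is observed at three timepoints — diagnosis, relapse and remission
— each with a mutant read count X and total depth N. Coordinates are 1-based
(VCF convention) throughout. Tables round-trip through a TSV dialect with a
fixed header or through VCF 4.x with per-sample allele depths (AD), where a
sample-name mapping assigns VCF samples to timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "TSV_COLUMNS",
    "VariantCall",
    "PresenceCall",
    "UndefinedMAFError",
    "compute_maf",
    "classify_presence",
    "read_variants",
    "write_variants",
    "write_vcf",
    "merge_platforms",
    "variants_to_frame",
    "frame_to_variants",
]

TIMEPOINTS = ("diagnosis", "relapse", "remission")

TSV_COLUMNS = [
    "case_id", "chrom", "pos", "ref", "alt",
    "dx_mut", "dx_tot", "rel_mut", "rel_tot", "rem_mut", "rem_tot",
    "diploid", "gene", "effect", "pathway",
]

_PREFIX = {"diagnosis": "dx", "relapse": "rel", "remission": "rem"}


class UndefinedMAFError(ValueError):
    """Raised when a MAF is requested at zero total depth."""


def compute_maf(mut_reads: int, total_reads: int) -> float:
    """Mutant allele fraction X/N.

    Undefined at zero depth; signalled with :class:`UndefinedMAFError`
    rather than returning a sentinel, so callers must decide explicitly.
    """
    if total_reads < 1:
        raise UndefinedMAFError("MAF undefined at zero total depth")
    if not (0 <= mut_reads <= total_reads):
        raise ValueError("mutant reads must lie in [0, total reads]")
    return mut_reads / total_reads


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant with read counts at the three timepoints."""

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    dx_mut: int
    dx_tot: int
    rel_mut: int
    rel_tot: int
    rem_mut: int = 0
    rem_tot: int = 0
    diploid: bool = True
    gene: str = ""
    effect: str = ""
    pathway: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for tp in TIMEPOINTS:
            x, n = self.counts(tp)
            if x < 0 or n < 0 or x > n:
                raise ValueError(
                    f"invalid counts at {tp}: mut={x}, total={n} "
                    "(require 0 <= mut <= total)"
                )

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.case_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    def counts(self, timepoint: str) -> tuple[int, int]:
        p = _PREFIX[timepoint]
        return getattr(self, f"{p}_mut"), getattr(self, f"{p}_tot")

    def maf(self, timepoint: str) -> float:
        return compute_maf(*self.counts(timepoint))


@dataclass(frozen=True)
class PresenceCall:
    """Per-timepoint presence of the mutant allele and derived category.

    ``category`` is one of ``dx_specific``, ``rel_specific`` or ``shared``;
    it is ``None`` (and ``flagged`` is True) for a variant absent from both
    tumour samples, which has no place in the clonal analysis.
    """

    diagnosis: str
    relapse: str
    remission: str
    category: str | None

    @property
    def flagged(self) -> bool:
        return self.category is None


def classify_presence(
    variant: VariantCall, maf_floor: float = 0.01, min_reads: int = 3
) -> PresenceCall:
    """Call the mutant allele present/absent at each timepoint.

    Present iff MAF >= ``maf_floor`` AND mutant reads >= ``min_reads`` on
    the (combined-platform) depth; the floor is the lower limit at which a
    mutant allele is considered reliably detected at the study's depths.
    """
    status = {}
    for tp in TIMEPOINTS:
        x, n = variant.counts(tp)
        present = n >= 1 and x >= min_reads and (x / n) >= maf_floor
        status[tp] = "present" if present else "absent"
    dx, rel = status["diagnosis"] == "present", status["relapse"] == "present"
    if dx and rel:
        category: str | None = "shared"
    elif dx:
        category = "dx_specific"
    elif rel:
        category = "rel_specific"
    else:
        category = None
    return PresenceCall(
        diagnosis=status["diagnosis"],
        relapse=status["relapse"],
        remission=status["remission"],
        category=category,
    )


# ---------------------------------------------------------------------------
# TSV / DataFrame I/O
# ---------------------------------------------------------------------------

def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "case_id": v.case_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt,
            "dx_mut": v.dx_mut, "dx_tot": v.dx_tot,
            "rel_mut": v.rel_mut, "rel_tot": v.rel_tot,
            "rem_mut": v.rem_mut, "rem_tot": v.rem_tot,
            "diploid": v.diploid, "gene": v.gene,
            "effect": v.effect, "pathway": v.pathway,
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def frame_to_variants(df: pd.DataFrame) -> list[VariantCall]:
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    variants: list[VariantCall] = []
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            variants.append(
                VariantCall(
                    case_id=str(row.case_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    dx_mut=int(row.dx_mut), dx_tot=int(row.dx_tot),
                    rel_mut=int(row.rel_mut), rel_tot=int(row.rel_tot),
                    rem_mut=int(row.rem_mut), rem_tot=int(row.rem_tot),
                    diploid=_parse_bool(row.diploid),
                    gene=_opt_str(row.gene),
                    effect=_opt_str(row.effect),
                    pathway=_opt_str(row.pathway),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: one for the header row, one for 1-based line numbering
            errors.append(f"line {idx + 2}: {exc}")
    if errors:
        raise ValueError("malformed variant rows:\n" + "\n".join(errors))
    return variants


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes"}
    return bool(x)


def _opt_str(x) -> str:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return ""
    return str(x)


def write_variants(variants: Iterable[VariantCall], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variants(
    path: str | Path,
    format: str = "tsv",
    sample_map: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Read a variant table from TSV or VCF.

    For VCF, ``sample_map`` maps timepoint names (``diagnosis``, ``relapse``,
    ``remission``) to VCF sample names; allele depths are taken from the
    per-sample AD field. Rows violating count invariants are reported with
    their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "case_id": str})
        return frame_to_variants(df)
    if format == "vcf":
        return _read_vcf(path, sample_map)
    raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# VCF I/O (per-sample allele depths, trio samples mapped to timepoints)
# ---------------------------------------------------------------------------

def _read_vcf(
    path: Path, sample_map: Mapping[str, str] | None
) -> list[VariantCall]:
    from cyvcf2 import VCF

    if sample_map is None:
        raise ValueError("reading VCF requires a sample->timepoint mapping")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        col = {tp: samples.index(sample_map[tp]) for tp in TIMEPOINTS}
    except (KeyError, ValueError) as exc:
        raise ValueError(
            f"sample_map must name VCF samples for {TIMEPOINTS}: {exc}"
        ) from exc
    variants = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(
                f"missing AD (allele depth) at {rec.CHROM}:{rec.POS}"
            )
        counts = {}
        for tp, i in col.items():
            ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
            counts[f"{_PREFIX[tp]}_mut"] = alt_d
            counts[f"{_PREFIX[tp]}_tot"] = ref_d + alt_d
        info = dict(rec.INFO)
        variants.append(
            VariantCall(
                case_id=str(info.get("CASE", "")),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                diploid=bool(int(info.get("DIPLOID", 1))),
                gene=str(info.get("GENE", "") or ""),
                effect=str(info.get("EFFECT", "") or ""),
                pathway=str(info.get("PATHWAY", "") or ""),
                **counts,
            )
        )
    return variants


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CASE,Number=1,Type=String,Description="Case identifier">
##INFO=<ID=DIPLOID,Number=1,Type=Integer,Description="Copy-neutral locus flag">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">
##INFO=<ID=PATHWAY,Number=1,Type=String,Description="Pathway label">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(
    variants: Sequence[VariantCall],
    path: str | Path,
    sample_map: Mapping[str, str],
) -> None:
    """Write variants as an uncompressed VCF 4.2 with per-sample AD."""
    sample_names = [sample_map[tp] for tp in TIMEPOINTS]
    lines = [_VCF_HEADER.rstrip("\n")]
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    for v in sorted(variants, key=lambda v: (contigs.index(v.chrom), v.pos)):
        info_parts = [f"CASE={v.case_id}", f"DIPLOID={int(v.diploid)}"]
        for tag, val in (("GENE", v.gene), ("EFFECT", v.effect),
                         ("PATHWAY", v.pathway)):
            if val:
                info_parts.append(f"{tag}={val}")
        ads = []
        for tp in TIMEPOINTS:
            x, n = v.counts(tp)
            ads.append(f"{n - x},{x}")
        lines.append(
            "\t".join(
                [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                 ";".join(info_parts), "AD"] + ads
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Platform merging
# ---------------------------------------------------------------------------

def merge_platforms(
    calls_a: Sequence[VariantCall], calls_b: Sequence[VariantCall]
) -> list[VariantCall]:
    """Combine read counts from two sequencing platforms per variant.

    Mutant and total reads are summed per timepoint for variants present in
    both lists (matched on case/chrom/pos/ref/alt); variants present in only
    one list pass through unchanged. Conflicting annotations on a shared key
    raise.
    """
    by_key_b = {}
    for v in calls_b:
        if v.key in by_key_b:
            raise ValueError(f"duplicate variant key in second list: {v.key}")
        by_key_b[v.key] = v
    merged: list[VariantCall] = []
    seen_a = set()
    for a in calls_a:
        if a.key in seen_a:
            raise ValueError(f"duplicate variant key in first list: {a.key}")
        seen_a.add(a.key)
        b = by_key_b.pop(a.key, None)
        if b is None:
            merged.append(a)
            continue
        if a.diploid != b.diploid:
            raise ValueError(f"conflicting diploid flags for {a.key}")
        merged.append(
            replace(
                a,
                dx_mut=a.dx_mut + b.dx_mut, dx_tot=a.dx_tot + b.dx_tot,
                rel_mut=a.rel_mut + b.rel_mut, rel_tot=a.rel_tot + b.rel_tot,
                rem_mut=a.rem_mut + b.rem_mut, rem_tot=a.rem_tot + b.rem_tot,
            )
        )
    merged.extend(by_key_b.values())
    return merged
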