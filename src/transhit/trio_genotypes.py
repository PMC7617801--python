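"""Trio genotypes, genotype-level QC and transmission phasing.

A variant in a proband can be phased without read-backed methods whenever the
trio genotypes identify the transmitting parent: a heterozygous proband allele
carried by exactly one parent was transmitted by that parent.  Two variants in
one gene are *in trans* when they were transmitted by different parents, which
is the configuration required for a compound heterozygote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

log = logging.getLogger(__name__)


class UndefinedVafError(ValueError):
    """Raised when allele fraction is requested with zero informative reads."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized biallelic variant identity (VCF-style 1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # matches the chr:pos:ref:alt convention
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open genomic interval occupied by the REF allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce (pos, ref, alt) to minimal representation.

    Shared trailing bases are trimmed first, then shared leading bases (keeping
    at least one base on each allele, advancing ``pos``), so indels keep one
    shared leading base as in left-normalized VCF records.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Transmission(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    DE_NOVO = "de_novo"
    AMBIGUOUS = "ambiguous"
    UNTYPED = "untyped"


@dataclass(frozen=True)
class TrioGenotype:
    """One biallelic variant's genotype and QC evidence in a single trio."""

    key: VariantKey
    proband_gt: Genotype
    mother_gt: Genotype
    father_gt: Genotype
    proband_dp: int | None = None
    proband_ad_ref: int | None = None
    proband_ad_alt: int | None = None
    filter_status: str = "PASS"


def vaf(ad_ref: int, ad_alt: int) -> float:
    """Variant allele fraction alt/(ref+alt) from allele depths."""
    total = ad_ref + ad_alt
    if total <= 0:
        raise UndefinedVafError("no informative reads: ad_ref + ad_alt == 0")
    return ad_alt / total


def passes_genotype_qc(
    g: TrioGenotype,
    min_depth: int = 6,
    vaf_low: float = 0.25,
    vaf_high: float = 0.75,
) -> bool:
    """Proband-level genotype QC.

    A call passes when the record FILTER is PASS, proband depth is at least
    ``min_depth`` and the proband allele fraction lies within
    ``[vaf_low, vaf_high]`` (bounds inclusive).  Missing evidence fails QC.
    """
    if g.filter_status != "PASS":
        return False
    if g.proband_dp is None or g.proband_dp < min_depth:
        return False
    if g.proband_ad_ref is None or g.proband_ad_alt is None:
        log.debug("QC fail (missing AD) at %s", g.key)
        return False
    try:
        frac = vaf(g.proband_ad_ref, g.proband_ad_alt)
    except UndefinedVafError:
        log.debug("QC fail (zero AD total) at %s", g.key)
        return False
    return vaf_low <= frac <= vaf_high


_CARRIER = (Genotype.HET, Genotype.HOM_ALT)


def classify_transmission(g: TrioGenotype) -> Transmission:
    """Assign the transmitting parent for a heterozygous proband variant.

    Requires a heterozygous proband.  A parent with a missing genotype makes
    the variant untyped; two carrier parents make it ambiguous (the
    transmitting haplotype cannot be resolved without read-backed phasing);
    two hom-ref parents make it de novo.
    """
    if g.proband_gt != Genotype.HET:
        raise ValueError(f"transmission is defined for het probands only, got {g.proband_gt}")
    if g.mother_gt == Genotype.MISSING or g.father_gt == Genotype.MISSING:
        return Transmission.UNTYPED
    mother_carrier = g.mother_gt in _CARRIER
    father_carrier = g.father_gt in _CARRIER
    if mother_carrier and father_carrier:
        return Transmission.AMBIGUOUS
    if mother_carrier:
        return Transmission.MATERNAL
    if father_carrier:
        return Transmission.PATERNAL
    return Transmission.DE_NOVO


def in_trans(a: Transmission, b: Transmission) -> bool:
    """True when two phased variants were transmitted by different parents."""
    phased = (Transmission.MATERNAL, Transmission.PATERNAL)
    if a not in phased or b not in phased:
        raise ValueError(f"in_trans requires resolved parental transmission, got ({a}, {b})")
    return a != b


# ---------------------------------------------------------------------------
# multiallelic decomposition
# ---------------------------------------------------------------------------

def decompose_record(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Sequence[tuple[int, int]],
) -> list[tuple[VariantKey, list[tuple[int, int]]]]:
    """Split a (possibly multiallelic) record into biallelic components.

    ``genotypes`` are per-sample allele-index pairs (-1 for missing).  For alt
    allele ``i`` the component genotype keeps allele 1 where the original
    allele index was ``i+1``, 0 where it was any other called allele, and -1
    where it was missing.
    """
    out = []
    for i, alt in enumerate(alts):
        key = normalize_key(chrom, pos, ref, alt)
        comp = []
        for a1, a2 in genotypes:
            comp.append(tuple(
                (-1 if a < 0 else (1 if a == i + 1 else 0)) for a in (a1, a2)
            ))
        out.append((key, comp))
    return out


def recompose_genotypes(
    components: Sequence[Sequence[tuple[int, int]]],
) -> list[tuple[int, int]]:
    """Inverse of :func:`decompose_record` over the genotype columns.

    Each sample slot is assigned alt index ``i+1`` if component ``i`` carries
    allele 1 in that slot; at most one component may claim a slot.
    """
    n_samples = len(components[0])
    merged: list[tuple[int, int]] = []
    for s in range(n_samples):
        slots = []
        for hap in (0, 1):
            claimed = [i for i, comp in enumerate(components) if comp[s][hap] == 1]
            if len(claimed) > 1:
                raise ValueError("inconsistent decomposition: slot claimed by multiple alts")
            if any(comp[s][hap] == -1 for comp in components):
                slots.append(-1)
            elif claimed:
                slots.append(claimed[0] + 1)
            else:
                slots.append(0)
        merged.append((slots[0], slots[1]))
    return merged


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

def _gt_from_dosage(dosage: tuple[int, int]) -> Genotype:
    if -1 in dosage:
        return Genotype.MISSING
    n = sum(dosage)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n]


def read_trio_vcf(
    vcf_path: str | Path,
    proband_id: str,
    father_id: str,
    mother_id: str,
) -> list[TrioGenotype]:
    """Parse a single-trio VCF into :class:`TrioGenotype` records.

    Multiallelic records are decomposed to biallelic keys; keys are
    minimal-representation normalized.  DP/AD are taken from the proband
    sample; missing FORMAT fields are carried as ``None`` (and then fail QC).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    idx = {s: i for i, s in enumerate(vcf.samples)}
    for role, sid in (("proband", proband_id), ("father", father_id), ("mother", mother_id)):
        if sid not in idx:
            raise KeyError(f"{role} sample {sid!r} not found in {vcf_path}")
    ip, ifa, imo = idx[proband_id], idx[father_id], idx[mother_id]

    records: list[TrioGenotype] = []
    for var in vcf:
        gts = [(g[0], g[1]) for g in var.genotypes]
        dp = var.format("DP")
        ad = var.format("AD")
        flt = var.FILTER or "PASS"
        for alt_i, (key, comp) in enumerate(
            decompose_record(var.CHROM, var.POS, var.REF, var.ALT, gts)
        ):
            proband_dp = int(dp[ip][0]) if dp is not None and dp[ip][0] >= 0 else None
            if ad is not None and ad.shape[1] > alt_i + 1:
                ad_ref = int(ad[ip][0])
                ad_alt = int(ad[ip][alt_i + 1])
                if ad_ref < 0 or ad_alt < 0:
                    ad_ref = ad_alt = None
            else:
                ad_ref = ad_alt = None
            records.append(TrioGenotype(
                key=key,
                proband_gt=_gt_from_dosage(comp[ip]),
                mother_gt=_gt_from_dosage(comp[imo]),
                father_gt=_gt_from_dosage(comp[ifa]),
                proband_dp=proband_dp,
                proband_ad_ref=ad_ref,
                proband_ad_alt=ad_alt,
                filter_status=flt,
            ))
    vcf.close()
    return records


@dataclass(frozen=True)
class Trio:
    """A pedigree row: proband with both parents and the trio's VCF path."""

    proband_id: str
    father_id: str
    mother_id: str
    vcf_path: str


def read_pedigree(ped_path: str | Path) -> list[Trio]:
    """Read a pedigree TSV (proband_id, father_id, mother_id, vcf_path)."""
    import pandas as pd

    df = pd.read_csv(ped_path, sep="\t", dtype=str)
    required = {"proband_id", "father_id", "mother_id", "vcf_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    return [
        Trio(r.proband_id, r.father_id, r.mother_id, r.vcf_path)
        for r in df.itertuples(index=False)
    ]
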