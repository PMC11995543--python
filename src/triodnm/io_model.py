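"""Input parsing and shared domain types.

Loads a multi-sample VCF (biallelic SNVs with per-sample GT/AD/DP/GQ and
site-level GATK annotations) together with a 6-column PED pedigree into the
in-memory types the rest of the pipeline operates on: :class:`SampleCall`,
:class:`SiteRecord` and :class:`Pedigree`.

Coordinates are VCF 1-based throughout. INFO annotations that htslib stores
as float32 are normalised to 4 decimal places on read so that a write/read
round trip reproduces identical :class:`SiteRecord` values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

logger = logging.getLogger("triodnm")

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)
BASES = ("A", "C", "G", "T")

#: cyvcf2 gt_types codes -> genotype labels
_GT_CODE = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


class ParseError(ValueError):
    """A VCF or PED file could not be parsed; message names the offending line."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call at one site.

    ``ref_reads``/``alt_reads`` come from the AD field and may sum to less
    than ``depth`` (clipped or otherwise uncounted reads), but each is
    bounded by ``depth`` individually. ``genotype_quality`` is Phred-scaled;
    it is ignored when the genotype is missing.
    """

    sample_id: str
    genotype: str
    ref_reads: int
    alt_reads: int
    depth: int
    genotype_quality: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if min(self.ref_reads, self.alt_reads, self.depth) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def alt_fraction(self) -> float:
        """Alternative read fraction; 0.0 at zero depth."""
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class SiteRecord:
    """A biallelic SNV site with its INFO annotations and per-sample calls.

    Rank-sum annotations are genuinely absent at sites without heterozygous
    reference-supporting reads; absence is represented as ``None``, never
    coerced to zero (filter semantics for absent values live in
    :mod:`triodnm.dnm_calling`).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qd: float | None
    fs: float | None
    mq: float | None
    mq_rank_sum: float | None
    read_pos_rank_sum: float | None
    allele_count: int
    calls: Mapping[str, SampleCall]

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos} alleles must be single bases, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")
        if self.pos < 1:
            raise ValueError("positions are 1-based")


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: str

    @property
    def parents(self) -> frozenset[str]:
        return frozenset(p for p in (self.sire, self.dam) if p is not None)


@dataclass(frozen=True)
class Trio:
    sire: str
    dam: str
    proband: str

    @property
    def id(self) -> str:
        return self.proband

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.proband, self.sire, self.dam)


class Pedigree:
    """Pedigree with derived trio / sib / descendant relations.

    A trio is any individual whose sire and dam are both known. Sib sets
    follow the shared-parent rule: any individual sharing at least one
    parent with the proband (half or full sib) counts — a full sib can
    legitimately inherit the same parental-mosaic mutation, so it receives
    the same screening exemption.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._ind: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._ind:
                raise ParseError(f"duplicate individual id {ind.id!r}")
            self._ind[ind.id] = ind
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ConfigurationError(
                    f"pedigree cycle: {' -> '.join(stack + [iid])}"
                )
            state[iid] = 0
            ind = self._ind.get(iid)
            if ind is not None:
                for p in ind.parents:
                    visit(p, stack + [iid])
            state[iid] = 1

        for iid in self._ind:
            visit(iid, [])

    def __contains__(self, iid: str) -> bool:
        return iid in self._ind

    def __len__(self) -> int:
        return len(self._ind)

    @property
    def individuals(self) -> dict[str, Individual]:
        return dict(self._ind)

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._ind[iid]
        except KeyError:
            raise KeyError(f"unknown individual {iid!r}") from None

    def trios(self) -> list[Trio]:
        out = []
        for ind in self._ind.values():
            if ind.sire is not None and ind.dam is not None:
                out.append(Trio(sire=ind.sire, dam=ind.dam, proband=ind.id))
        return sorted(out, key=lambda t: t.proband)

    def offspring_of(self, iid: str) -> set[str]:
        self[iid]
        return {
            o.id for o in self._ind.values() if iid in o.parents
        }

    def sibs_of(self, iid: str) -> set[str]:
        """Individuals sharing >=1 parent with ``iid`` (half and full sibs)."""
        me = self[iid]
        if not me.parents:
            return set()
        out = set()
        for other in self._ind.values():
            if other.id != iid and other.parents & me.parents:
                out.add(other.id)
        return out

    def descendants_of(self, iid: str) -> set[str]:
        self[iid]
        out: set[str] = set()
        frontier = {iid}
        while frontier:
            nxt: set[str] = set()
            for parent in frontier:
                for child in self.offspring_of(parent):
                    if child not in out:
                        out.add(child)
                        nxt.add(child)
            frontier = nxt
        return out

    def generation_depths(self, founder: str) -> dict[str, int]:
        """Pedigree depth from ``founder``: founder is generation 1, its
        offspring generation 2, etc. (minimum depth over paths)."""
        depths = {founder: 1}
        frontier = {founder}
        while frontier:
            nxt: set[str] = set()
            for iid in frontier:
                for child in self.offspring_of(iid):
                    d = depths[iid] + 1
                    if child not in depths or d < depths[child]:
                        depths[child] = d
                        nxt.add(child)
            frontier = nxt
        return depths


def derive_relatives(ped: Pedigree, proband: str) -> tuple[set[str], set[str]]:
    """Sib set (shared-parent rule) and offspring set for the
    population-screen exemption."""
    return ped.sibs_of(proband), ped.offspring_of(proband)


# ---------------------------------------------------------------------------
# PED / VCF reading

def read_ped(path: str | Path) -> Pedigree:
    """Parse a 6-column PED file (fam, id, sire, dam, sex, phenotype;
    0 = unknown parent)."""
    inds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 PED columns, got "
                    f"{len(fields)}"
                )
            _fam, iid, sire, dam, sex, _pheno = fields[:6]
            inds.append(
                Individual(
                    id=iid,
                    sire=None if sire == "0" else sire,
                    dam=None if dam == "0" else dam,
                    sex=sex,
                )
            )
    return Pedigree(inds)


def _info_float(variant, key: str) -> float | None:
    val = variant.INFO.get(key)
    if val is None:
        return None
    f = float(val)
    if math.isnan(f):
        return None
    return round(f, 4)


def read_cohort(
    vcf_path: str | Path,
    ped_path: str | Path,
    contigs: Sequence[str] | None = None,
) -> tuple[list[SiteRecord], Pedigree, dict[str, int]]:
    """Load a cohort VCF and pedigree.

    Multi-allelic and non-SNV records are skipped (counted in the returned
    skip dictionary under ``"multiallelic"`` / ``"non_snv"``); with a contig
    whitelist, off-whitelist records count under ``"off_contig"``. Every
    pedigree individual whose trio is derivable must have a VCF sample
    column, otherwise a :class:`ConfigurationError` is raised.
    """
    ped = read_ped(ped_path)
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {vcf_path}: {exc}") from exc

    samples = list(vcf.samples)
    sample_set = set(samples)
    for trio in ped.trios():
        for member in trio.members:
            if member not in sample_set:
                raise ConfigurationError(
                    f"trio member {member!r} declared in {ped_path} has no "
                    f"sample column in {vcf_path}"
                )

    whitelist = set(contigs) if contigs is not None else None
    skipped = {"multiallelic": 0, "non_snv": 0, "off_contig": 0}
    records: list[SiteRecord] = []
    for v in vcf:
        if whitelist is not None and v.CHROM not in whitelist:
            skipped["off_contig"] += 1
            continue
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or not v.is_snp:
            skipped["non_snv"] += 1
            continue
        records.append(_variant_to_record(v, samples))
    if any(skipped.values()):
        logger.info(
            "skipped records: %s",
            ", ".join(f"{k}={n}" for k, n in skipped.items() if n),
        )
    return records, ped, skipped


def _variant_to_record(v, samples: list[str]) -> SiteRecord:
    ad = v.format("AD")
    dp = v.format("DP")
    gq = v.format("GQ")
    gt_types = v.gt_types
    calls = {}
    for i, sid in enumerate(samples):
        geno = _GT_CODE[int(gt_types[i])]
        ref_reads = int(ad[i][0]) if ad is not None and ad[i][0] >= 0 else 0
        alt_reads = int(ad[i][1]) if ad is not None and ad[i][1] >= 0 else 0
        depth = int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else 0
        qual = float(gq[i][0]) if gq is not None and gq[i][0] >= 0 else 0.0
        calls[sid] = SampleCall(
            sample_id=sid,
            genotype=geno,
            ref_reads=ref_reads,
            alt_reads=alt_reads,
            depth=depth,
            genotype_quality=qual,
        )
    ac = v.INFO.get("AC")
    if ac is None:
        ac = sum(
            {HET: 1, HOM_ALT: 2}.get(c.genotype, 0) for c in calls.values()
        )
    return SiteRecord(
        chrom=v.CHROM,
        pos=v.POS,
        ref_allele=v.REF,
        alt_allele=v.ALT[0],
        qd=_info_float(v, "QD"),
        fs=_info_float(v, "FS"),
        mq=_info_float(v, "MQ"),
        mq_rank_sum=_info_float(v, "MQRankSum"),
        read_pos_rank_sum=_info_float(v, "ReadPosRankSum"),
        allele_count=int(ac),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Writers (plain-text VCF/PED emission; htslib not required for output)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count in genotypes">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def _fmt_info(rec: SiteRecord) -> str:
    parts = [f"AC={rec.allele_count}"]
    for key, val in (
        ("QD", rec.qd),
        ("FS", rec.fs),
        ("MQ", rec.mq),
        ("MQRankSum", rec.mq_rank_sum),
        ("ReadPosRankSum", rec.read_pos_rank_sum),
    ):
        if val is not None:
            parts.append(f"{key}={val:.4f}")
    return ";".join(parts)


def write_vcf(
    records: Sequence[SiteRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as an uncompressed VCF 4.2 file.

    ``samples`` fixes the column order; every record must carry a call for
    each sample.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            cols = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref_allele,
                rec.alt_allele,
                ".",
                "PASS",
                _fmt_info(rec),
                "GT:AD:DP:GQ",
            ]
            for sid in samples:
                c = rec.calls[sid]
                cols.append(
                    f"{_GT_STRING[c.genotype]}:{c.ref_reads},{c.alt_reads}:"
                    f"{c.depth}:{int(round(c.genotype_quality))}"
                )
            fh.write("\t".join(cols) + "\n")


def write_ped(ped: Pedigree, path: str | Path, family: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for ind in sorted(ped.individuals.values(), key=lambda i: i.id):
            fh.write(
                f"{family}\t{ind.id}\t{ind.sire or 0}\t{ind.dam or 0}\t"
                f"{ind.sex}\t0\n"
            )


def write_fasta(
    sequences: Mapping[str, str], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
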