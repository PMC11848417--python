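"""VCF input and the two-stage SNP filter cascade.

Stage one is the GATK-style hard filter on site annotations:
FS <= 60, HaplotypeScore <= 13.0, MQ >= 40, QD >= 2,
ReadPosRankSum >= -8.0 and MQRankSum > -12.5 (note the single strict
inequality). An absent annotation passes its criterion — rank-sum
annotations are undefined at sites without both allele classes, and
discarding such sites would be spurious.

Stage two is the PLINK-style population-genetics filter, applied in a
fixed order so the minor-allele frequency reflects usable calls:
(1) genotypes with depth < 3 are set missing, (2) loci with missing
fraction > 0.2 are dropped, (3) loci with MAF < 0.05 on the remaining
calls are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from fawtrack.core import GenotypeMatrix

log = logging.getLogger(__name__)

HARD_FILTER_INFO_KEYS = (
    "FS", "HaplotypeScore", "MQ", "QD", "ReadPosRankSum", "MQRankSum",
)


@dataclass
class VariantRecord:
    """One biallelic SNP: site annotations plus per-sample calls."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    info: dict[str, float]        # hard-filter annotations, keys optional
    dosages: np.ndarray           # per-sample, NaN = missing
    depths: np.ndarray


@dataclass
class FilterConfig:
    """Thresholds of both filter stages (defaults are the hard-filter
    criteria and PLINK-style parameters described in the module docs)."""

    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_min: float = 40.0
    qd_min: float = 2.0
    read_pos_rank_sum_min: float = -8.0
    mq_rank_sum_gt: float = -12.5
    depth_min: int = 3
    maf_min: float = 0.05
    missing_max: float = 0.2

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"threshold {f} must be finite")


@dataclass
class FilterSummary:
    """Counts at each step of the cascade (per-criterion for the hard
    filter, per-stage for the population-genetics filter)."""

    n_input: int = 0
    n_dropped_multiallelic: int = 0
    hard_fail_counts: dict[str, int] = field(default_factory=dict)
    n_after_hard: int = 0
    n_genotypes_set_missing: int = 0
    n_dropped_missing: int = 0
    n_dropped_maf: int = 0
    n_final: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tcount\n")
            fh.write(f"input_records\t{self.n_input}\n")
            fh.write(f"dropped_multiallelic_or_non_snp\t{self.n_dropped_multiallelic}\n")
            for crit, n in self.hard_fail_counts.items():
                fh.write(f"hard_filter_fail_{crit}\t{n}\n")
            fh.write(f"after_hard_filters\t{self.n_after_hard}\n")
            fh.write(f"genotypes_set_missing_low_depth\t{self.n_genotypes_set_missing}\n")
            fh.write(f"loci_dropped_missing_rate\t{self.n_dropped_missing}\n")
            fh.write(f"loci_dropped_maf\t{self.n_dropped_maf}\n")
            fh.write(f"final_loci\t{self.n_final}\n")


def read_pop_map(path) -> dict[str, str]:
    """Read a 2-column sample<TAB>population file."""
    pop_map: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            pop_map[sample] = pop
    return pop_map


def read_vcf(
    path, pop_map: dict[str, str] | None = None
) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a multi-sample VCF into records plus a genotype matrix.

    Multiallelic and non-SNP records are dropped (count logged). Samples
    missing from ``pop_map`` are retained in the matrix but carry no
    population label, which excludes them from population statistics.
    """
    pop_map = pop_map or {}
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_map and pop_map:
            log.warning("sample %s has no population label", s)

    records: list[VariantRecord] = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        info = {}
        for key in HARD_FILTER_INFO_KEYS:
            val = var.INFO.get(key)
            if val is not None:
                info[key] = val
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=missing
        dos = np.asarray(var.gt_types, dtype=float)
        dos[dos == 3] = np.nan
        dp = var.format("DP")
        depths = (
            np.full(len(samples), -1, dtype=int)
            if dp is None
            else np.asarray(dp, dtype=int).reshape(-1)
        )
        records.append(
            VariantRecord(
                chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0],
                info=info, dosages=dos, depths=depths,
            )
        )
    vcf.close()
    if n_dropped:
        log.info("dropped %d multiallelic/non-SNP records", n_dropped)
    matrix = records_to_matrix(records, samples, pop_map)
    matrix._n_dropped_multiallelic = n_dropped  # carried for summaries
    return records, matrix


def records_to_matrix(
    records: list[VariantRecord],
    samples: list[str],
    pop_map: dict[str, str] | None = None,
) -> GenotypeMatrix:
    n = len(samples)
    if records:
        dosages = np.stack([r.dosages for r in records], axis=1)
        depths = np.stack([r.depths for r in records], axis=1)
    else:
        dosages = np.empty((n, 0))
        depths = np.empty((n, 0), dtype=int)
    return GenotypeMatrix(
        samples=samples,
        loci=[(r.chrom, r.pos) for r in records],
        dosages=dosages,
        depths=depths,
        pop_labels={s: p for s, p in (pop_map or {}).items() if s in samples},
    )


# ---------------------------------------------------------------------------
# stage 1: hard filters on site annotations
# ---------------------------------------------------------------------------

def _criteria(config: FilterConfig):
    return {
        "FS": lambda x: x <= config.fs_max,
        "HaplotypeScore": lambda x: x <= config.haplotype_score_max,
        "MQ": lambda x: x >= config.mq_min,
        "QD": lambda x: x >= config.qd_min,
        "ReadPosRankSum": lambda x: x >= config.read_pos_rank_sum_min,
        "MQRankSum": lambda x: x > config.mq_rank_sum_gt,   # strict
    }


def apply_hard_filters(
    records: list[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Keep records passing every site-annotation criterion.

    Absent annotations pass their criterion; a non-numeric annotation
    fails the record with a logged parse error. Returns the survivors
    and per-criterion fail counts (a record failing several criteria is
    counted under each).
    """
    config = config or FilterConfig()
    crits = _criteria(config)
    fail_counts = {k: 0 for k in crits}
    fail_counts["parse_error"] = 0
    survivors = []
    for rec in records:
        ok = True
        for key, test in crits.items():
            if key not in rec.info:
                continue
            try:
                val = float(rec.info[key])
            except (TypeError, ValueError):
                log.error("non-numeric %s at %s:%d", key, rec.chrom, rec.pos)
                fail_counts["parse_error"] += 1
                ok = False
                continue
            if not test(val):
                fail_counts[key] += 1
                ok = False
        if ok:
            survivors.append(rec)
    return survivors, fail_counts


# ---------------------------------------------------------------------------
# stage 2: PLINK-style genotype/locus filters
# ---------------------------------------------------------------------------

def apply_popgen_filters(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterSummary]:
    """Depth → missingness → MAF cascade on the genotype matrix.

    All loci removed is a legal outcome: the returned matrix is simply
    empty. The summary reports counts at each step.
    """
    config = config or FilterConfig()
    summary = FilterSummary(n_input=matrix.n_loci)

    dosages = matrix.dosages.copy()
    if matrix.depths is not None:
        low = (matrix.depths < config.depth_min) & ~np.isnan(dosages)
        summary.n_genotypes_set_missing = int(low.sum())
        dosages[low] = np.nan

    n = dosages.shape[0]
    with np.errstate(invalid="ignore"):
        miss_frac = np.isnan(dosages).sum(axis=0) / max(n, 1)
    keep_missing = miss_frac <= config.missing_max
    summary.n_dropped_missing = int((~keep_missing).sum())

    n_called = (~np.isnan(dosages)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = np.where(n_called > 0, maf >= config.maf_min, False)
    summary.n_dropped_maf = int((keep_missing & ~keep_maf).sum())

    keep = keep_missing & keep_maf
    summary.n_final = int(keep.sum())
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        loci=[l for l, k in zip(matrix.loci, keep) if k],
        dosages=dosages[:, keep],
        depths=None if matrix.depths is None else matrix.depths[:, keep],
        pop_labels=dict(matrix.pop_labels),
    )
    return out, summary


def filter_vcf(
    vcf_path, pop_map: dict[str, str], config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterSummary]:
    """Full cascade: read → hard filters → population-genetics filters."""
    config = config or FilterConfig()
    records, matrix = read_vcf(vcf_path, pop_map)
    survivors, fail_counts = apply_hard_filters(records, config)
    surv_matrix = records_to_matrix(survivors, matrix.samples, pop_map)
    out, summary = apply_popgen_filters(surv_matrix, config)
    summary.n_input = len(records)
    summary.n_dropped_multiallelic = getattr(matrix, "_n_dropped_multiallelic", 0)
    summary.hard_fail_counts = fail_counts
    summary.n_after_hard = len(survivors)
    return out, summary
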