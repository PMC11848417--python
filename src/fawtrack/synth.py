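"""Synthetic structured genotypes and analytic wind fields.

Genotypes follow the Balding–Nichols model: an ancestral allele
frequency p is drawn per locus, and each population's frequency is a
Beta draw with mean p and variance p(1-p)*F, so Weir & Cockerham's
theta has a known target F. Admixed individuals draw each allele from
one of two parental populations. Wind fields are closed-form regimes
(uniform, easterly trades, seasonally reversing monsoon, solid-body
rotation) over toy rectangular continents, so every downstream flight
rule can be checked against arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fawtrack.core import GenotypeMatrix
from fawtrack.wind import WindField

EARTH_RADIUS_M = 6_371_000.0

#: INFO keys written to synthetic VCFs, with the (low, high) range their
#: default values are drawn from — all inside the hard-filter bounds.
_INFO_RANGES = {
    "FS": (0.0, 50.0),
    "HaplotypeScore": (0.0, 12.0),
    "MQ": (41.0, 60.0),
    "QD": (3.0, 30.0),
    "ReadPosRankSum": (-6.0, 6.0),
    "MQRankSum": (-6.0, 6.0),
}


@dataclass
class GenotypeSimConfig:
    """Parameters of the structured-genotype simulation.

    ``fst_target`` is the Balding–Nichols F: the expected Weir &
    Cockerham differentiation among the simulated populations. ``F = 0``
    is legal and collapses every population onto the ancestral
    frequency. ``admixture_spec`` entries are
    ``(pop_a, pop_b, alpha, n_individuals)``: each admixed individual
    draws each allele from ``pop_a`` with probability ``alpha``, else
    from ``pop_b``.
    """

    n_pops: int = 2
    n_per_pop: int = 20
    n_loci: int = 1000
    fst_target: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    mean_depth: float = 20.0
    admixture_spec: list[tuple[str, str, float, int]] = field(default_factory=list)
    pop_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_per_pop, self.n_loci) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for pa, pb, alpha, n in self.admixture_spec:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError("admixture alpha must lie in [0, 1]")
            if n < 1:
                raise ValueError("admixture n_individuals must be positive")
        if self.pop_names is not None and len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")


def simulate_genotypes(config: GenotypeSimConfig) -> tuple[GenotypeMatrix, dict]:
    """Draw a structured genotype matrix plus a ground-truth record.

    Returns
    -------
    matrix : GenotypeMatrix
        Population samples first (``<pop>_<i>``), then admixed
        individuals labelled ``<pop_a>x<pop_b>``.
    truth : dict
        Ancestral frequencies ``p``, per-population frequencies ``p_k``
        (pop × locus), the Balding–Nichols ``F``, and admixture labels.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    F = config.fst_target
    pops = config.pop_names or [f"pop{k + 1}" for k in range(config.n_pops)]

    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=L)
    if F > 0.0:
        scale = (1.0 - F) / F
        p_k = rng.beta(p * scale, (1.0 - p) * scale, size=(config.n_pops, L))
    else:
        # Beta degenerates to a point mass at p.
        p_k = np.tile(p, (config.n_pops, 1))

    samples: list[str] = []
    pop_labels: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for k, pop in enumerate(pops):
        g = rng.binomial(2, p_k[k], size=(config.n_per_pop, L)).astype(float)
        rows.append(g)
        for i in range(config.n_per_pop):
            name = f"{pop}_{i + 1}"
            samples.append(name)
            pop_labels[name] = pop

    admix_labels: dict[str, tuple[str, str, float]] = {}
    for pa, pb, alpha, n_ind in config.admixture_spec:
        ia, ib = pops.index(pa), pops.index(pb)
        label = f"{pa}x{pb}"
        for i in range(n_ind):
            src = rng.random(size=(2, L)) < alpha          # True -> pop_a
            p_src = np.where(src, p_k[ia], p_k[ib])
            alleles = (rng.random(size=(2, L)) < p_src).astype(float)
            rows.append(alleles.sum(axis=0, keepdims=True))
            name = f"{label}_{i + 1}"
            samples.append(name)
            pop_labels[name] = label
            admix_labels[name] = (pa, pb, alpha)

    dosages = np.vstack(rows)
    if config.missing_rate > 0.0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    depths = rng.poisson(config.mean_depth, size=dosages.shape)
    while (zero := depths < 1).any():  # truncate Poisson at >= 1
        depths[zero] = rng.poisson(config.mean_depth, size=int(zero.sum()))

    loci = [("chr1", 100 * (j + 1)) for j in range(L)]
    matrix = GenotypeMatrix(
        samples=samples, loci=loci, dosages=dosages,
        depths=depths, pop_labels=pop_labels,
    )
    truth = {
        "p": p,
        "p_k": p_k,
        "F": F,
        "populations": pops,
        "admixture": admix_labels,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# wind fields
# ---------------------------------------------------------------------------

@dataclass
class WindSimConfig:
    """Analytic wind regimes on a regular grid.

    regime
        ``uniform``: constant (u0, v0). ``trade_easterly``: u = -|u0|,
        v = 0 (flow from east to west, the trade-wind analogue).
        ``monsoon_reversal``: u = +|u0| before ``switch_time``, -|u0|
        after (seasonally reversing monsoon). ``rotational``:
        solid-body rotation about the grid centre with angular velocity
        ``omega`` (u = -omega*dy, v = +omega*dx, dx/dy in metres).
    continents
        (lon_min, lon_max, lat_min, lat_max) rectangles marked as land.
    """

    regime: str = "uniform"
    u0: float = 10.0
    v0: float = 0.0
    lon_min: float = -10.0
    lon_max: float = 10.0
    lat_min: float = -10.0
    lat_max: float = 10.0
    d_lon: float = 1.0
    d_lat: float = 1.0
    levels: tuple[float, ...] = (500.0, 1000.0, 1500.0, 2000.0)
    time_start: str = "2018-06-01T00:00"
    time_end: str = "2018-06-05T00:00"
    d_t_hours: float = 6.0
    continents: list[tuple[float, float, float, float]] = field(default_factory=list)
    switch_time: str | None = None          # monsoon reversal instant
    omega: float | None = None              # rad/s; default u0 at 1000 km
    terrain_height: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in {"uniform", "trade_easterly", "monsoon_reversal", "rotational"}:
            raise ValueError(f"unknown wind regime {self.regime!r}")
        if self.d_lon <= 0 or self.d_lat <= 0 or self.d_t_hours <= 0:
            raise ValueError("grid steps must be positive")
        if any(lv <= 0 for lv in self.levels):
            raise ValueError("levels must be positive altitudes")


def simulate_wind_field(config: WindSimConfig) -> WindField:
    """Materialise the configured analytic regime on its grid."""
    lons = np.arange(config.lon_min, config.lon_max + 1e-9, config.d_lon)
    lats = np.arange(config.lat_min, config.lat_max + 1e-9, config.d_lat)
    t0 = np.datetime64(config.time_start, "s")
    t1 = np.datetime64(config.time_end, "s")
    step = np.timedelta64(int(round(config.d_t_hours * 3600)), "s")
    times = np.arange(t0, t1 + step, step)
    if times.size < 2:
        raise ValueError("wind field needs at least 2 time steps")
    levels = np.asarray(config.levels, dtype=float)

    shape = (times.size, levels.size, lats.size, lons.size)
    u = np.zeros(shape)
    v = np.zeros(shape)
    if config.regime == "uniform":
        u[:] = config.u0
        v[:] = config.v0
    elif config.regime == "trade_easterly":
        u[:] = -abs(config.u0)
        v[:] = 0.0
    elif config.regime == "monsoon_reversal":
        switch = (
            np.datetime64(config.switch_time, "s")
            if config.switch_time is not None
            else times[0] + (times[-1] - times[0]) // 2
        )
        before = times < switch
        u[before] = abs(config.u0)
        u[~before] = -abs(config.u0)
        v[:] = 0.0
    elif config.regime == "rotational":
        omega = config.omega if config.omega is not None else config.u0 / 1e6
        lat_c = 0.5 * (lats[0] + lats[-1])
        lon_c = 0.5 * (lons[0] + lons[-1])
        deg = np.pi / 180.0
        dy = (lats - lat_c) * deg * EARTH_RADIUS_M                    # (lat,)
        dx = (lons - lon_c) * deg * EARTH_RADIUS_M * np.cos(lat_c * deg)
        u[:] = (-omega * dy)[None, None, :, None]
        v[:] = (omega * dx)[None, None, None, :]

    landmask = np.zeros((lats.size, lons.size), dtype=bool)
    for lon_a, lon_b, lat_a, lat_b in config.continents:
        landmask |= (
            (lats[:, None] >= lat_a) & (lats[:, None] <= lat_b)
            & (lons[None, :] >= lon_a) & (lons[None, :] <= lon_b)
        )
    terrain = np.full((lats.size, lons.size), float(config.terrain_height))
    return WindField(
        times=times, levels=levels, lats=lats, lons=lons,
        u=u, v=v, landmask=landmask, terrain=terrain,
    )


# ---------------------------------------------------------------------------
# synthetic VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=fawtrack-synth
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Consistency of the site with at most two segregating haplotypes">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read mapping qualities">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##contig=<ID=chr1>
"""

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_synthetic_vcf(
    matrix: GenotypeMatrix,
    path,
    info_spec: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
) -> None:
    """Write the matrix as a VCF 4.2 with GT:DP genotypes.

    Default INFO values are drawn inside the hard-filter bounds;
    ``info_spec`` maps locus index → INFO overrides, used to force
    chosen records to violate chosen filter criteria.
    """
    if matrix.n_samples == 0 or matrix.n_loci == 0:
        raise ValueError("refusing to write an empty matrix")
    rng = np.random.default_rng(seed)
    info_spec = info_spec or {}
    contigs = sorted({c for c, _ in matrix.loci})
    header = _VCF_HEADER
    if contigs != ["chr1"]:
        header = header.replace(
            "##contig=<ID=chr1>\n",
            "".join(f"##contig=<ID={c}>\n" for c in contigs),
        )
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    lines = [header + cols + "\t" + "\t".join(matrix.samples)]
    depths = (
        matrix.depths
        if matrix.depths is not None
        else np.full(matrix.dosages.shape, 20, dtype=int)
    )
    for j, (chrom, pos) in enumerate(matrix.loci):
        info = {k: rng.uniform(lo, hi) for k, (lo, hi) in _INFO_RANGES.items()}
        info.update(info_spec.get(j, {}))
        info_str = ";".join(f"{k}={info[k]:.4g}" for k in _INFO_RANGES if k in info)
        gts = [
            f"{_GT_CODE.get(matrix.dosages[i, j], './.')}:{int(depths[i, j])}"
            for i in range(matrix.n_samples)
        ]
        lines.append(
            f"{chrom}\t{pos}\t.\tA\tG\t100\tPASS\t{info_str}\tGT:DP\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pop_map(matrix: GenotypeMatrix, path) -> None:
    """Write the sample → population map as 2-column TSV."""
    with open(path, "w") as fh:
        for s in matrix.samples:
            if s in matrix.pop_labels:
                fh.write(f"{s}\t{matrix.pop_labels[s]}\n")
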