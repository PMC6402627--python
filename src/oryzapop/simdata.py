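"""Synthetic two-species datasets for a selfing crop and its wild progenitor.

The generator emulates the statistical structure of a domestication study:
a structured, predominantly selfing wild population; a domesticate founded
from one wild deme through a severe bottleneck followed by exponential
recovery; geographic subpopulations arranged as a one-dimensional stepping
stone with coastal-style coordinates; localized hard sweeps; and a diverged
outgroup used for polarization. Every run carries a machine-readable truth
log so downstream statistics can be tested against known answers.

Backward-in-time coalescent histories come from msprime; selfing is modeled
as effective-size scaling plus genotype-level excess homozygosity (an
inbreeding coefficient F = s/(2-s) applied when pairing haplotypes into
diploids). Sweeps are imposed by post-hoc frequency distortion: linked
variation on each flank of the sweep site is homogenized from a donor onto
~95% of the target population, which produces the high-frequency derived
alleles and the flank-wise LD footprint that the omega statistic detects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .variantio import MISSING, GenotypeMatrix

_BASES = np.array(list("ACGT"))
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class Bottleneck:
    """Founding bottleneck of the domesticate.

    time: generations before present at which the domesticate lineage
        merges back into its source wild deme.
    severity: founding population size as a fraction of the wild deme size.
    recovery_growth_rate: per-generation exponential growth of each
        domesticated deme during the recovery/expansion phase.
    """

    time: float = 3000.0
    severity: float = 0.1
    recovery_growth_rate: float = 2e-3


@dataclass(frozen=True)
class Sweep:
    """A planted hard sweep: beneficial-allele frequency is driven to
    >= ``carrier_fraction`` in the target group and linked variation within
    ``width_bp`` of the position is homogenized flank by flank."""

    chrom: int  # 0-based chromosome index
    position: int  # bp, 1-based
    selection_coefficient: float = 0.1
    target: str = "dom"  # "dom", "wild", or a subpopulation name
    width_bp: int = 50_000
    carrier_fraction: float = 0.95


@dataclass(frozen=True)
class Introgression:
    """A planted gene haplotype: all samples of one domesticated
    subpopulation receive, homozygously, the alleles of a donor from a
    (typically distant) wild deme over the given interval."""

    chrom: int
    start: int
    end: int
    target_subpop: str = "OG-2"
    source_subpop: str = "OB-D"


# Default subpopulation coordinates: five domesticated demes along a coastal
# arc plus two inland, four wild demes inland, loosely West African.
_DOM_COORDS = [(14.5, -16.5), (11.5, -15.0), (8.5, -12.0), (11.0, -7.5), (13.5, -4.0)]
_WILD_COORDS = [(13.0, -5.0), (11.0, -2.0), (13.0, 1.0), (12.0, 4.0)]
_WILD_NAMES = "ABCD"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mimic a resequencing panel of a bottlenecked selfing
    domesticate and its structured wild progenitor at desk scale: wild
    per-deme diversity near 1.3e-3/site, a 5% founding bottleneck about
    3000 generations ago with subsequent expansion, selfing rate 0.9,
    and stepping-stone migration weak enough to maintain geographic
    structure and isolation by distance.
    """

    n_wild: int = 40
    n_dom: int = 45
    n_wild_subpops: int = 4
    n_dom_subpops: int = 5
    genome_length: int = 500_000
    n_chromosomes: int = 2
    mu: float = 6e-8
    recomb_rate: float = 1e-8
    selfing_rate: float = 0.9
    wild_deme_size: float = 5_000.0
    dom_deme_size: float = 20_000.0
    wild_migration: float = 2e-4
    dom_migration: float = 2e-4
    wild_split_time: float = 100_000.0
    bottleneck: Bottleneck = field(default_factory=Bottleneck)
    sweeps: list = field(default_factory=list)
    introgressions: list = field(default_factory=list)
    outgroup_divergence: float = 0.03
    geography: dict | None = None  # subpop -> (lat, lon); defaults used when None
    coord_jitter: float = 0.6
    missingness_rate: float = 0.02
    ref_is_ancestral_prob: float = 0.8
    transition_prob: float = 0.67
    functional_proportions: tuple = (0.70, 0.25, 0.05)  # noncoding, synonymous, nonsyn
    seed: int = 1

    def __post_init__(self):
        for name in ("selfing_rate", "missingness_rate", "ref_is_ancestral_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_wild < 0 or self.n_dom < 0 or self.n_wild + self.n_dom == 0:
            raise ValueError("need at least one sample")
        if not 0.0 < self.bottleneck.severity <= 1.0:
            raise ValueError("bottleneck severity must be in (0, 1]")
        if self.mu < 0:
            raise ValueError("mutation rate must be nonnegative")

    @property
    def inbreeding_coefficient(self) -> float:
        s = self.selfing_rate
        return s / (2.0 - s)

    @property
    def dom_subpop_names(self) -> list:
        return [f"OG-{k + 1}" for k in range(self.n_dom_subpops)]

    @property
    def wild_subpop_names(self) -> list:
        return [f"OB-{_WILD_NAMES[k % 4]}{k // 4 or ''}" for k in range(self.n_wild_subpops)]

    def subpop_coordinates(self) -> dict:
        if self.geography is not None:
            return dict(self.geography)
        coords = {}
        for k, name in enumerate(self.dom_subpop_names):
            coords[name] = _DOM_COORDS[k % len(_DOM_COORDS)]
        for k, name in enumerate(self.wild_subpop_names):
            coords[name] = _WILD_COORDS[k % len(_WILD_COORDS)]
        return coords


@dataclass
class TruthLog:
    """Ground truth for one simulated dataset."""

    sweep_sites: list  # (chrom_name, grid position bp) per planted sweep
    sweep_windows: list  # (chrom_name, start, end) homogenized interval
    theta_per_pop: dict  # population -> scaled mutation rate per site (4*Ne_eff*mu)
    subpop_of: dict  # sample id -> subpopulation name
    ancestral_allele: np.ndarray  # per variant, equals ref or alt
    functional_class: np.ndarray  # per variant
    outgroup_mutated: np.ndarray  # bool per variant: outgroup branch carried a substitution
    introgressed: list  # (chrom_name, start, end, target_subpop, source_subpop)
    haplotypes: np.ndarray | None = None  # (2*n_samples, n_variants) pre-distortion phases

    def to_json(self) -> str:
        payload = {
            "sweep_sites": self.sweep_sites,
            "sweep_windows": self.sweep_windows,
            "theta_per_pop": self.theta_per_pop,
            "subpop_of": self.subpop_of,
            "ancestral_allele": list(map(str, self.ancestral_allele)),
            "functional_class": list(map(str, self.functional_class)),
            "outgroup_mutated": [bool(x) for x in self.outgroup_mutated],
            "introgressed": self.introgressed,
        }
        return json.dumps(payload, indent=1)


def _build_demography(cfg: SimConfig) -> msprime.Demography:
    scale = 1.0 / (1.0 + cfg.inbreeding_coefficient)
    dem = msprime.Demography()
    wild = cfg.wild_subpop_names
    doms = cfg.dom_subpop_names if cfg.n_dom > 0 else []
    for name in wild:
        dem.add_population(name=_msname(name), initial_size=cfg.wild_deme_size * scale)
    n_b = cfg.bottleneck.severity * cfg.wild_deme_size
    if doms:
        g = cfg.bottleneck.recovery_growth_rate
        # recovery phase length implied by the growth rate; keep the
        # constant-size bottleneck phase at least 10% of the total time
        t_spread = math.log(cfg.dom_deme_size / n_b) / g if g > 0 else 0.9 * cfg.bottleneck.time
        t_spread = min(t_spread, 0.9 * cfg.bottleneck.time)
        for name in doms:
            dem.add_population(
                name=_msname(name),
                initial_size=cfg.dom_deme_size * scale,
                growth_rate=math.log(cfg.dom_deme_size / n_b) / t_spread,
            )
        dem.add_population(name="DOMFOUNDER", initial_size=n_b * scale)
    dem.add_population(
        name="ANC", initial_size=cfg.wild_deme_size * max(cfg.n_wild_subpops, 1) * scale
    )
    for a, b in zip(wild, wild[1:]):  # 1-D stepping stone
        dem.set_symmetric_migration_rate([_msname(a), _msname(b)], cfg.wild_migration)
    for a, b in zip(doms, doms[1:]):
        dem.set_symmetric_migration_rate([_msname(a), _msname(b)], cfg.dom_migration)
    if doms:
        dem.add_population_split(
            time=t_spread, derived=[_msname(d) for d in doms], ancestral="DOMFOUNDER"
        )
        # mass migration (not a split): the source wild deme keeps its own
        # samples and migration before the founding time
        dem.add_mass_migration(
            time=cfg.bottleneck.time, source="DOMFOUNDER", dest=_msname(wild[0]), proportion=1.0
        )
    dem.add_population_split(
        time=cfg.wild_split_time, derived=[_msname(w) for w in wild], ancestral="ANC"
    )
    dem.sort_events()
    return dem


def _msname(subpop: str) -> str:
    return subpop.replace("-", "_")


def _split_counts(total: int, k: int) -> list:
    base = total // k
    return [base + (1 if i < total % k else 0) for i in range(k)]


def _chrom_lengths(cfg: SimConfig) -> list:
    return _split_counts(cfg.genome_length, cfg.n_chromosomes)


def simulate_history(cfg: SimConfig):
    """Simulate the configured history.

    Returns ``(matrix, samples, truth)``: a :class:`GenotypeMatrix` of
    diploid codes, a sample table (id, species, subpop, lat, lon,
    coverage) and the :class:`TruthLog`.
    """
    rng = np.random.default_rng(cfg.seed)
    dem = _build_demography(cfg)
    wild_names, dom_names = cfg.wild_subpop_names, cfg.dom_subpop_names

    sample_sets, sample_subpops, sample_species = [], [], []
    for name, count in zip(wild_names, _split_counts(cfg.n_wild, cfg.n_wild_subpops)):
        if count:
            sample_sets.append(msprime.SampleSet(count, population=_msname(name), ploidy=2))
            sample_subpops += [name] * count
            sample_species += ["wild"] * count
    if cfg.n_dom > 0:
        for name, count in zip(dom_names, _split_counts(cfg.n_dom, cfg.n_dom_subpops)):
            if count:
                sample_sets.append(msprime.SampleSet(count, population=_msname(name), ploidy=2))
                sample_subpops += [name] * count
                sample_species += ["dom"] * count
    n_samples = len(sample_subpops)
    sample_ids = [f"{sp}_{i:03d}" for i, sp in enumerate(sample_subpops)]

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    hap_blocks, chrom_col, pos_col, anc_block = [], [], [], []
    for ci, (cname, clen) in enumerate(zip(chrom_names, _chrom_lengths(cfg))):
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=clen,
            recombination_rate=cfg.recomb_rate,
            random_seed=cfg.seed * 1000 + ci + 1,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=cfg.mu,
            model=msprime.BinaryMutationModel(),
            random_seed=cfg.seed * 1000 + ci + 501,
        )
        positions, haps = [], []
        for var in mts.variants():
            g = var.genotypes
            # binary model can stack mutations; keep strictly biallelic 0/1 sites
            if len(var.alleles) != 2 or g.max() > 1 or g.min() < 0 or g.max() == g.min():
                continue
            p = int(var.site.position) + 1
            if positions and p <= positions[-1]:
                continue  # discrete positions can collide; keep the first
            positions.append(p)
            haps.append(g.astype(np.int8))
        if positions:
            hap_blocks.append(np.array(haps, dtype=np.int8).T)  # (2n, S_chrom)
            chrom_col += [cname] * len(positions)
            pos_col += positions

    n_variants = len(pos_col)
    haplotypes = (
        np.concatenate(hap_blocks, axis=1) if n_variants else np.zeros((2 * n_samples, 0), np.int8)
    )
    chrom_arr = np.array(chrom_col, dtype=object)
    pos_arr = np.array(pos_col, dtype=np.int64)

    # allele labels: haplotype value 0 is ancestral; map onto REF/ALT bases
    anc_base = rng.choice(_BASES, size=n_variants)
    derived_base = np.array(
        [
            _TRANSITION_OF[b] if rng.random() < cfg.transition_prob else rng.choice(_tv(b))
            for b in anc_base
        ],
        dtype=object,
    )
    ref_is_anc = rng.random(n_variants) < cfg.ref_is_ancestral_prob
    ref = np.where(ref_is_anc, anc_base, derived_base).astype(object)
    alt = np.where(ref_is_anc, derived_base, anc_base).astype(object)

    # diploid pairing with genotype-level inbreeding: with probability F an
    # individual is autozygous and reuses its first haplotype twice
    f_coef = cfg.inbreeding_coefficient
    autozygous = rng.random(n_samples) < f_coef
    hap1 = haplotypes[0::2]
    hap2 = np.where(autozygous[:, None], hap1, haplotypes[1::2])
    derived_count = (hap1 + hap2).astype(np.int8)
    genotypes = np.where(ref_is_anc[None, :], derived_count, 2 - derived_count).astype(np.int8)
    phased = np.empty_like(haplotypes)
    phased[0::2], phased[1::2] = hap1, hap2
    phased = np.where(ref_is_anc[None, :], phased, 1 - phased).astype(np.int8)

    # sample metadata
    coords = cfg.subpop_coordinates()
    lat = np.array(
        [coords[sp][0] + rng.normal(0, cfg.coord_jitter) for sp in sample_subpops]
    )
    lon = np.array(
        [coords[sp][1] + rng.normal(0, cfg.coord_jitter) for sp in sample_subpops]
    )
    coverage = np.round(rng.lognormal(mean=2.6, sigma=0.45, size=n_samples), 2)
    samples = pd.DataFrame(
        {
            "id": sample_ids,
            "species": sample_species,
            "subpop": sample_subpops,
            "lat": np.round(lat, 4),
            "lon": np.round(lon, 4),
            "coverage": coverage,
        }
    )

    scale = 1.0 / (1.0 + f_coef)
    truth = TruthLog(
        sweep_sites=[],
        sweep_windows=[],
        theta_per_pop={
            "wild": 4 * cfg.wild_deme_size * scale * cfg.mu,
            "dom": 4 * cfg.dom_deme_size * scale * cfg.mu,
        },
        subpop_of=dict(zip(sample_ids, sample_subpops)),
        ancestral_allele=np.where(ref_is_anc, ref, alt).astype(object),
        functional_class=rng.choice(
            ["noncoding", "synonymous", "nonsynonymous"],
            size=n_variants,
            p=cfg.functional_proportions,
        ).astype(object),
        outgroup_mutated=rng.random(n_variants) < cfg.outgroup_divergence,
        introgressed=[],
        haplotypes=phased,
    )

    sample_idx = {sid: i for i, sid in enumerate(sample_ids)}
    species_arr = np.array(sample_species, dtype=object)
    subpop_arr = np.array(sample_subpops, dtype=object)

    for sw in cfg.sweeps:
        cname = chrom_names[sw.chrom]
        target = _target_mask(species_arr, subpop_arr, sw.target)
        _impose_sweep(genotypes, chrom_arr, pos_arr, cname, sw, target, rng)
        truth.sweep_sites.append((cname, int(sw.position)))
        truth.sweep_windows.append(
            (cname, int(sw.position - sw.width_bp), int(sw.position + sw.width_bp))
        )

    for intro in cfg.introgressions:
        cname = chrom_names[intro.chrom]
        in_region = (chrom_arr == cname) & (pos_arr >= intro.start) & (pos_arr <= intro.end)
        donors = np.flatnonzero(subpop_arr == intro.source_subpop)
        recipients = np.flatnonzero(subpop_arr == intro.target_subpop)
        if not len(donors) or not len(recipients):
            raise ValueError("introgression subpopulation has no samples")
        donor_row = genotypes[donors[0], in_region].copy()
        donor_row[donor_row == 1] = 2  # donated haplotype carried homozygously
        donor_row[donor_row == MISSING] = 0
        for r in recipients:
            genotypes[r, in_region] = donor_row
        genotypes[donors[0], in_region] = donor_row
        truth.introgressed.append(
            (cname, int(intro.start), int(intro.end), intro.target_subpop, intro.source_subpop)
        )

    if cfg.missingness_rate > 0:
        mask = rng.random(genotypes.shape) < cfg.missingness_rate
        genotypes = np.where(mask, MISSING, genotypes).astype(np.int8)

    annotations = _synthetic_annotations(rng, n_variants, n_samples)
    matrix = GenotypeMatrix(
        samples=sample_ids,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        annotations=annotations,
        functional_class=truth.functional_class.copy(),
    )
    matrix.validate()
    return matrix, samples, truth


def _tv(base: str):
    return [b for b in "ACGT" if b != base and b != _TRANSITION_OF[base]]


def _target_mask(species, subpop, target: str) -> np.ndarray:
    if target in ("dom", "wild"):
        return species == target
    return subpop == target


def _impose_sweep(genotypes, chrom, pos, cname, sw: Sweep, target: np.ndarray, rng) -> None:
    """Homogenize each flank of the sweep position from an independent donor
    onto a ``carrier_fraction`` subset of the target samples."""
    targets = np.flatnonzero(target)
    if len(targets) < 2:
        return
    for lo, hi in (
        (sw.position - sw.width_bp, sw.position),
        (sw.position, sw.position + sw.width_bp),
    ):
        sel = (chrom == cname) & (pos >= lo) & (pos <= hi)
        if not sel.any():
            continue
        donor = rng.choice(targets)
        donor_row = genotypes[donor, sel].copy()
        donor_row[donor_row == 1] = 2  # swept haplotype rides to homozygosity
        donor_row[donor_row == MISSING] = 0
        n_carriers = max(int(math.ceil(sw.carrier_fraction * len(targets))), 1)
        carriers = rng.choice(targets, size=n_carriers, replace=False)
        for c in carriers:
            genotypes[c, sel] = donor_row


def _synthetic_annotations(rng, n_variants: int, n_samples: int) -> dict:
    """GATK-style INFO annotations with plausible marginal distributions."""
    dp = rng.normal(loc=15.0 * n_samples, scale=4.0 * math.sqrt(max(n_samples, 1)), size=n_variants)
    return {
        "DP": np.round(np.clip(dp, 1, None)),
        "QD": np.round(np.clip(rng.gamma(shape=6.0, scale=4.0, size=n_variants), 0.1, 40.0), 2),
        "MQ": np.round(np.clip(rng.normal(58.0, 3.0, size=n_variants), 10, 60), 2),
        "MQRankSum": np.round(rng.normal(0.0, 1.0, size=n_variants), 3),
        "ReadPosRankSum": np.round(rng.normal(0.0, 1.0, size=n_variants), 3),
        "FS": np.round(rng.exponential(scale=3.0, size=n_variants), 3),
    }


def make_outgroup_map(
    matrix: GenotypeMatrix,
    truth: TruthLog,
    unaligned_frac: float = 0.0,
    gap_frac: float = 0.0,
    multimap_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a per-variant outgroup alignment map.

    Each variant carries the outgroup allele (the true ancestral allele
    unless the outgroup branch mutated in the truth log) and alignment
    flags drawn independently at the given fractions. Flagged-unaligned
    variants have no outgroup allele.
    """
    if unaligned_frac + gap_frac + multimap_frac > 1.0 + 1e-12:
        raise ValueError("flag fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    n = matrix.n_variants
    u = rng.random(n)
    unaligned = u < unaligned_frac
    gap5 = (u >= unaligned_frac) & (u < unaligned_frac + gap_frac)
    multi = (u >= unaligned_frac + gap_frac) & (u < unaligned_frac + gap_frac + multimap_frac)
    allele = truth.ancestral_allele.astype(object).copy()
    for i in np.flatnonzero(truth.outgroup_mutated):
        allele[i] = rng.choice([b for b in "ACGT" if b != allele[i]])
    allele[unaligned] = ""
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.pos,
            "outgroup_allele": allele,
            "unaligned": unaligned,
            "gap5": gap5,
            "multimap": multi,
        }
    )


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as a VCF 4.2 text file with GT and INFO annotations."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=oryzapop-simdata\n')
        for c in dict.fromkeys(matrix.chrom):  # preserve order
            sub = matrix.pos[matrix.chrom == c]
            fh.write(f"##contig=<ID={c},length={int(sub.max()) + 10_000 if len(sub) else 1}>\n")
        for name, typ in [
            ("DP", "Integer"),
            ("QD", "Float"),
            ("MQ", "Float"),
            ("MQRankSum", "Float"),
            ("ReadPosRankSum", "Float"),
            ("FS", "Float"),
        ]:
            fh.write(f'##INFO=<ID={name},Number=1,Type={typ},Description="{name}">\n')
        fh.write('##INFO=<ID=FC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        fc = matrix.functional_class
        for j in range(matrix.n_variants):
            info = []
            for name in ("DP", "QD", "MQ", "MQRankSum", "ReadPosRankSum", "FS"):
                if name in matrix.annotations and not math.isnan(matrix.annotations[name][j]):
                    v = matrix.annotations[name][j]
                    info.append(f"{name}={int(v)}" if name == "DP" else f"{name}={v:g}")
            if fc is not None and fc[j]:
                info.append(f"FC={fc[j]}")
            gts = "\t".join(_VCF_GT[int(g)] for g in matrix.genotypes[:, j])
            fh.write(
                f"{matrix.chrom[j]}\t{matrix.pos[j]}\t.\t{matrix.ref[j]}\t{matrix.alt[j]}"
                f"\t.\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def write_bundle(matrix: GenotypeMatrix, samples: pd.DataFrame, truth: TruthLog, outdir,
                 outgroup_map: pd.DataFrame | None = None,
                 features: pd.DataFrame | None = None,
                 qmatrix: pd.DataFrame | None = None) -> dict:
    """Write the full dataset bundle (VCF, sample TSV, outgroup map TSV,
    GFF3 features, Q-matrix TSV, truth JSON) and return the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "variants.vcf",
        "samples": outdir / "samples.tsv",
        "outgroup_map": outdir / "outgroup_map.tsv",
        "features": outdir / "features.gff3",
        "qmatrix": outdir / "qmatrix.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(matrix, paths["vcf"])
    samples.to_csv(paths["samples"], sep="\t", index=False)
    if outgroup_map is None:
        outgroup_map = make_outgroup_map(matrix, truth)
    outgroup_map.to_csv(paths["outgroup_map"], sep="\t", index=False)
    if features is None:
        features = default_features(matrix)
    write_gff3(features, paths["features"])
    if qmatrix is None:
        qmatrix = truth_qmatrix(samples, seed=0)
    qmatrix.to_csv(paths["qmatrix"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    return paths


def default_features(matrix: GenotypeMatrix, n_per_chrom: int = 4, width: int = 4000,
                     seed: int = 0) -> pd.DataFrame:
    """Evenly spaced candidate-gene intervals along each chromosome."""
    rows = []
    k = 0
    for c in dict.fromkeys(matrix.chrom):
        sub = matrix.pos[matrix.chrom == c]
        if not len(sub):
            continue
        span = int(sub.max())
        for i in range(n_per_chrom):
            start = int((i + 0.5) * span / n_per_chrom)
            rows.append(
                {"chrom": c, "start": start, "end": start + width, "gene_id": f"gene{k:02d}"}
            )
            k += 1
    return pd.DataFrame(rows)


def write_gff3(features: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in features.iterrows():
            fh.write(
                f"{row.chrom}\tsimdata\tgene\t{int(row.start)}\t{int(row.end)}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]),
                    "end": int(f[4]),
                    "gene_id": attrs.get("ID", f"feature{len(rows)}"),
                }
            )
    return pd.DataFrame(rows)


def truth_qmatrix(samples: pd.DataFrame, concentration: float = 60.0, seed: int = 0
                  ) -> pd.DataFrame:
    """Ancestry fractions concentrated on each sample's true subpopulation,
    standing in for a model-based admixture fit."""
    rng = np.random.default_rng(seed)
    subpops = list(dict.fromkeys(samples["subpop"]))
    k = len(subpops)
    rows = []
    for _, s in samples.iterrows():
        alpha = np.ones(k)
        alpha[subpops.index(s["subpop"])] = concentration
        rows.append(rng.dirichlet(alpha))
    q = pd.DataFrame(rows, columns=subpops)
    q.insert(0, "sample", list(samples["id"]))
    return q


def neutral_config(n_samples: int = 50, genome_length: int = 500_000,
                   target_snps: int = 5000, seed: int = 1, **kw) -> SimConfig:
    """A single constant-size panmictic population with no selfing, no
    bottleneck and no sweeps; mutation rate tuned so the expected number of
    segregating sites is ``target_snps`` (Watterson expectation)."""
    n_hap = 2 * n_samples
    a1 = sum(1.0 / i for i in range(1, n_hap))
    ne = 10_000.0
    base = dict(
        n_wild=n_samples,
        n_dom=0,
        n_wild_subpops=1,
        n_dom_subpops=1,
        genome_length=genome_length,
        n_chromosomes=1,
        selfing_rate=0.0,
        wild_deme_size=ne,
        missingness_rate=0.0,
        seed=seed,
    )
    base.update(kw)
    total_bp = base["genome_length"] * base["n_chromosomes"]
    base.setdefault("mu", target_snps / (4 * ne * a1 * total_bp))
    return SimConfig(**base)


def sweep_config(n_samples: int = 40, genome_length: int = 1_000_000,
                 sweep_position: int | None = None, seed: int = 1, **kw) -> SimConfig:
    """Single population on a neutral background with one planted hard
    sweep at the genome midpoint (selfing rate 0.5, ~8 SNPs/kb), the
    standard validation scenario for the LD sweep scan."""
    pos = genome_length // 2 if sweep_position is None else sweep_position
    return SimConfig(
        n_wild=n_samples,
        n_dom=0,
        n_wild_subpops=1,
        genome_length=genome_length,
        n_chromosomes=1,
        mu=4e-8,
        wild_deme_size=10_000.0,
        selfing_rate=0.5,
        missingness_rate=0.0,
        sweeps=[Sweep(chrom=0, position=pos, target="wild")],
        seed=seed,
        **kw,
    )


def stepping_stone_config(n_samples: int = 40, n_demes: int = 4, migration: float = 2.5e-5,
                          seed: int = 1, **kw) -> SimConfig:
    """Wild-only 1-D stepping stone used for isolation-by-distance checks."""
    return SimConfig(
        n_wild=n_samples,
        n_dom=0,
        n_wild_subpops=n_demes,
        wild_migration=migration,
        coord_jitter=0.2,
        seed=seed,
        **kw,
    )


def panmictic_config(n_samples: int = 40, seed: int = 1, **kw) -> SimConfig:
    """Single wild deme with scattered coordinates: geography carries no
    information about relatedness."""
    cfg = SimConfig(
        n_wild=n_samples,
        n_dom=0,
        n_wild_subpops=1,
        coord_jitter=4.0,
        seed=seed,
        **kw,
    )
    return cfg
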