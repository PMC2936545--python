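"""Synthetic expression / genotype / lipid-trait generator.

The generator emulates the statistical structure of a population blood
transcriptomics study: clusters of tightly co-expressed probes driven by
shared latent factors ("modules"), lipid traits with sex-specific means and
standard deviations, medication covariates at realistic prevalences,
technical replicate arrays with bead counts, cis- and trans-acting genetic
effects on expression, and SNP "causal anchors" that impose a chosen causal
topology between a trait and a module's latent factor.

Every draw flows from ``SimulationConfig.seed`` through per-stage
``numpy.random.default_rng`` streams, so each generation step is
bit-reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GenotypeDataset, TraitTable

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_expression",
    "generate_genotypes",
    "generate_traits",
    "generate_dataset",
    "DEFAULT_TRAIT_SPECS",
]

TOPOLOGIES = ("causal", "reactive", "confounded", "independent")


@dataclass(frozen=True)
class TraitSpec:
    """Target moments for one lipid trait, overall and per sex."""

    name: str
    mean: float
    sd: float
    male_mean: float
    male_sd: float
    female_mean: float
    female_sd: float


#: Blood lipid panel of a Finnish population cohort: total cholesterol,
#: LDL/HDL cholesterol, apolipoproteins A1 and B, triglycerides and fasting
#: free fatty acids (mmol/L except apolipoproteins in g/L).
DEFAULT_TRAIT_SPECS = (
    TraitSpec("TC", 5.11, 0.95, 5.09, 0.95, 5.13, 0.95),
    TraitSpec("LDL", 3.07, 0.84, 3.17, 0.84, 2.98, 0.83),
    TraitSpec("HDL", 1.48, 0.36, 1.34, 0.30, 1.61, 0.36),
    TraitSpec("APOA1", 1.63, 0.28, 1.53, 0.25, 1.72, 0.28),
    TraitSpec("APOB", 0.92, 0.21, 0.95, 0.21, 0.89, 0.20),
    TraitSpec("TG", 1.15, 0.64, 1.27, 0.78, 1.04, 0.47),
    TraitSpec("FFA", 0.36, 0.21, 0.33, 0.20, 0.38, 0.22),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    The defaults describe the study conditions the pipeline targets: ~500
    unrelated samples, a 1000-probe co-expression panel containing five
    planted modules, hypertension/cholesterol medication prevalences of
    20.5% / 14.3%, and a "causal" topology in which the anchored lipid
    trait (TG) drives the first module's latent factor.
    """

    n_samples: int = 500
    n_probes: int = 1000
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (40, 30, 25, 20, 15)
    module_factor_sd: float = 1.0
    noise_sd: float = 1.0
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_effect: float = 0.8
    n_cis_eqtls: int = 5
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAIT_SPECS
    htm_prevalence: float = 0.205
    cm_prevalence: float = 0.143
    causal_topology: str = "causal"
    #: trait anchored to the first module's factor via the causal topology
    anchored_trait: str = "TG"
    #: variance of a node explained by its anchor SNP
    anchor_r2: float = 0.10
    #: structural path between the anchored trait and the module factor
    cross_path: float = 0.5
    #: extra (trait, module-index) loadings applied on the Z-score scale
    trait_loadings: dict = field(
        default_factory=lambda: {("HDL", 1): 0.3, ("APOB", 1): -0.3}
    )
    #: technical replicate noise (log2 sd) and corrupted-sample fraction
    replicate_sd: float = 0.15
    corrupt_fraction: float = 0.05
    #: fraction of background probes flagged non-autosomal/globin/multimapping
    flagged_fraction: float = 0.10
    genotype_missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules != len(self.module_sizes):
            raise ValueError("n_modules must equal len(module_sizes)")
        if sum(self.module_sizes) > self.n_probes:
            raise ValueError("module_sizes exceed n_probes")
        if any(s < 10 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 10")
        if self.module_factor_sd <= 0:
            raise ValueError("module_factor_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.maf_range[0] <= self.maf_range[1] < 0.5 + 1e-12):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for p in (self.htm_prevalence, self.cm_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must be in [0, 1]")
        if self.causal_topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown causal_topology {self.causal_topology!r}; "
                f"expected one of {TOPOLOGIES}"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Record of everything that was planted, for recovery tests."""

    module_assignment: pd.Series  # probe -> module index (0 = background)
    latent_factors: pd.DataFrame  # modules x samples
    probe_loadings: pd.Series  # probe -> loading on its module factor
    eqtl_map: dict  # snp id -> (probe id, per-allele effect)
    anchor_map: dict  # snp id -> (node name, topology)
    trait_loadings: pd.DataFrame | None = None  # traits x modules
    confounder: np.ndarray | None = None
    # generation-internal couplings (anchor dosages and the structural
    # standardized value of the anchored trait) needed by later stages
    anchor_dosages: dict = field(default_factory=dict)
    trait_core: np.ndarray | None = None


def _hwe_dosages(rng: np.random.Generator, maf: float, n: int) -> np.ndarray:
    """Hardy-Weinberg draw: two independent allele copies at frequency maf."""
    return rng.binomial(2, maf, size=n).astype(float)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_expression(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate the probes x samples matrix and its ground-truth record.

    Module probes follow a single-factor model ``loading * factor + noise``
    with probe loadings drawn uniform [0.6, 1]; background probes are
    independent noise around probe-specific baselines. Two technical
    replicates per sample (linear scale, with bead counts) are attached so
    the replicate-QC stage has something to chew on; a ``corrupt_fraction``
    of samples get one replicate with 10x inflated noise.
    """
    rng = config.rng(0)
    n, p = config.n_samples, config.n_probes
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    probes = pd.Index([f"P{i:05d}" for i in range(p)], name="probe")

    # --- structural core: anchors, optional confounder, trait core, factor 1
    g_factor = _hwe_dosages(rng, 0.3, n)
    g_trait = _hwe_dosages(rng, 0.3, n)
    a = np.sqrt(config.anchor_r2)
    b = config.cross_path
    gf, gt = _standardize(g_factor), _standardize(g_trait)
    confounder = None
    topo = config.causal_topology
    if topo == "causal":
        t_core = a * gt + np.sqrt(1 - a**2) * rng.standard_normal(n)
        resid = 1 - a**2 - b**2
        f1 = b * t_core + a * gf + np.sqrt(max(resid, 1e-9)) * rng.standard_normal(n)
    elif topo == "reactive":
        f1 = a * gf + np.sqrt(1 - a**2) * rng.standard_normal(n)
        resid = 1 - a**2 - b**2
        t_core = b * f1 + a * gt + np.sqrt(max(resid, 1e-9)) * rng.standard_normal(n)
    elif topo == "confounded":
        confounder = rng.standard_normal(n)
        resid = 1 - a**2 - b**2
        f1 = a * gf + b * confounder + np.sqrt(max(resid, 1e-9)) * rng.standard_normal(n)
        t_core = a * gt + b * confounder + np.sqrt(max(resid, 1e-9)) * rng.standard_normal(n)
    else:  # independent
        f1 = a * gf + np.sqrt(1 - a**2) * rng.standard_normal(n)
        t_core = a * gt + np.sqrt(1 - a**2) * rng.standard_normal(n)

    # --- latent factors (factor 1 carries the causal topology)
    factors = np.empty((config.n_modules, n))
    if config.n_modules:
        factors[0] = f1 * config.module_factor_sd
        for m in range(1, config.n_modules):
            factors[m] = rng.standard_normal(n) * config.module_factor_sd
    factor_index = pd.Index(
        [f"M{m + 1}" for m in range(config.n_modules)], name="module"
    )

    # --- expression values
    assignment = np.zeros(p, dtype=int)
    loadings = np.zeros(p)
    values = np.zeros((p, n))  # background probes are pure noise + baseline
    baselines = rng.uniform(6, 12, size=p)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        idx = slice(pos, pos + size)
        assignment[idx] = m
        lam = rng.uniform(0.6, 1.0, size=size)
        loadings[idx] = lam
        values[idx] = lam[:, None] * factors[m - 1][None, :]
        pos += size
    values += rng.standard_normal((p, n)) * config.noise_sd
    values += baselines[:, None]

    # --- annotations: genome layout of 2 chromosomes x 100 Mb
    chrom = np.where(rng.random(p) < 0.5, "1", "2")
    position = rng.integers(1, 100_000_000, size=p)
    globin = np.zeros(p, dtype=bool)
    n_mappings = np.ones(p, dtype=int)
    background = np.flatnonzero(assignment == 0)
    n_flag = int(round(config.flagged_fraction * p))
    flagged = rng.choice(background, size=min(n_flag, background.size), replace=False)
    third = max(1, flagged.size // 3)
    chrom = chrom.astype(object)
    for j in flagged[:third]:
        chrom[j] = "X"
    globin[flagged[third : 2 * third]] = True
    n_mappings[flagged[2 * third :]] = 2

    annotations = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": position,
            "globin": globin,
            "n_mappings": n_mappings,
            "true_module": assignment,
        },
        index=probes,
    )

    # --- technical replicates (linear scale) with bead counts
    from .preprocess import ReplicatePair  # local import to avoid a cycle

    n_corrupt = int(round(config.corrupt_fraction * n))
    corrupt = set(rng.choice(n, size=n_corrupt, replace=False).tolist())
    replicates: dict[str, ReplicatePair] = {}
    for i, sid in enumerate(samples):
        sds = [config.replicate_sd, config.replicate_sd]
        if i in corrupt:
            sds[int(rng.integers(2))] *= 10.0
        reps = [
            2.0 ** (values[:, i] + rng.standard_normal(p) * sd) for sd in sds
        ]
        beads = rng.integers(10, 61, size=(2, p))
        replicates[sid] = ReplicatePair(
            sample_id=sid,
            s1=pd.Series(reps[0], index=probes),
            s2=pd.Series(reps[1], index=probes),
            b1=pd.Series(beads[0], index=probes),
            b2=pd.Series(beads[1], index=probes),
            corrupted=i in corrupt,
        )

    expr = ExpressionDataset(
        pd.DataFrame(values, index=probes, columns=samples),
        annotations,
        replicates,
    )
    truth = GroundTruth(
        module_assignment=pd.Series(assignment, index=probes, name="module"),
        latent_factors=pd.DataFrame(factors, index=factor_index, columns=samples),
        probe_loadings=pd.Series(loadings, index=probes, name="loading"),
        eqtl_map={},
        anchor_map={},
        confounder=confounder,
        anchor_dosages={"factor": g_factor, "trait": g_trait},
        trait_core=t_core,
    )
    return expr, truth


def generate_genotypes(config: SimulationConfig, truth: GroundTruth) -> GenotypeDataset:
    """Generate the samples x SNPs dosage panel and plant genetic effects.

    Background SNPs are independent Hardy-Weinberg draws at MAFs uniform on
    ``maf_range``. ``n_cis_eqtls`` SNPs are placed within 100 kb of a target
    probe's midpoint and shift that probe by ``cis_effect`` noise-SDs per
    minor allele (the shift is added to the expression matrix in place).
    The two anchor SNPs drawn during expression generation are embedded in
    the panel far (> 5 Mb) from the module probes, so the factor anchor
    acts in trans on every module-1 probe.
    """
    rng = config.rng(1)
    n = config.n_samples
    n_snps = config.n_snps
    samples = truth.latent_factors.columns
    ids, chroms, positions, dosage_cols = [], [], [], []

    # anchors first: re-use the dosages the structural core was built on
    anchor_nodes = [("factor", "rs_anchor_factor"), ("trait", "rs_anchor_trait")]
    for node, snp_id in anchor_nodes:
        ids.append(snp_id)
        chroms.append("2")
        positions.append(int(rng.integers(50_000_000, 100_000_000)))
        dosage_cols.append(truth.anchor_dosages[node].copy())
        truth.anchor_map[snp_id] = (node, config.causal_topology)

    n_background = n_snps - len(ids) - config.n_cis_eqtls
    if n_background < 0:
        raise ValueError("n_snps too small for the planted SNPs")

    maf_lo, maf_hi = config.maf_range
    for k in range(n_background):
        maf = rng.uniform(maf_lo, maf_hi)
        ids.append(f"rs{k:06d}")
        chroms.append("1" if rng.random() < 0.5 else "2")
        positions.append(int(rng.integers(1, 100_000_000)))
        dosage_cols.append(_hwe_dosages(rng, maf, n))

    # cis eQTLs: target probes spread over modules and background
    probes = truth.module_assignment.index
    ann_chrom = None
    targets = rng.choice(len(probes), size=config.n_cis_eqtls, replace=False)
    for j, t in enumerate(targets):
        maf = rng.uniform(max(maf_lo, 0.2), maf_hi)
        dos = _hwe_dosages(rng, maf, n)
        snp_id = f"rs_cis{j:03d}"
        ids.append(snp_id)
        truth.eqtl_map[snp_id] = (probes[t], config.cis_effect)
        # provisional coordinates; moved next to the target probe by
        # apply_cis_effects once probe annotations are known
        chroms.append("1")
        positions.append(int(rng.integers(1, 100_000_000)))
        dosage_cols.append(dos)

    dosages = np.column_stack(dosage_cols)

    # missingness on background SNPs only (planted signals stay complete)
    if config.genotype_missing_rate > 0:
        mask = rng.random(dosages.shape) < config.genotype_missing_rate
        mask[:, : len(anchor_nodes)] = False
        mask[:, len(anchor_nodes) + n_background :] = False
        dosages = dosages.astype(float)
        dosages[mask] = np.nan

    snps = pd.DataFrame(
        {"chromosome": chroms, "position": positions},
        index=pd.Index(ids, name="snp"),
    )
    gd = GenotypeDataset(
        pd.DataFrame(dosages, index=samples, columns=snps.index), snps
    )
    return gd


def apply_cis_effects(
    expr: ExpressionDataset, genotypes: GenotypeDataset, truth: GroundTruth,
    config: SimulationConfig,
) -> None:
    """Add the planted per-allele shifts to their target probes (in place)
    and place each cis SNP within 100 kb of its target probe's midpoint."""
    rng = config.rng(3)
    for snp_id, (probe, effect) in truth.eqtl_map.items():
        dos = genotypes.dosages[snp_id].to_numpy(dtype=float)
        dos = np.nan_to_num(dos, nan=np.nanmean(dos))
        shift = effect * config.noise_sd * dos
        expr.values.loc[probe] += shift
        if expr.replicates:
            for i, sid in enumerate(expr.values.columns):
                pair = expr.replicates.get(sid)
                if pair is not None:
                    pair.s1.loc[probe] *= 2.0 ** shift[i]
                    pair.s2.loc[probe] *= 2.0 ** shift[i]
        if expr.annotations is not None:
            mid = int(expr.annotations.loc[probe, "position"])
            chrom = expr.annotations.loc[probe, "chromosome"]
            offset = int(rng.integers(-100_000, 100_001))
            genotypes.snps.loc[snp_id, "position"] = max(1, mid + offset)
            genotypes.snps.loc[snp_id, "chromosome"] = chrom


def generate_traits(config: SimulationConfig, truth: GroundTruth) -> TraitTable:
    """Generate the trait table: lipids with sex-specific moments, module
    couplings on the Z-score scale, and covariates (age, sex, HTM, CM,
    alcohol).

    The anchored trait's standardized value is the structural ``trait_core``
    drawn with the latent factors (so the causal topology holds exactly);
    other traits combine ``trait_loadings`` on standardized factors with
    independent Gaussian noise scaled to unit variance. Raw values are then
    ``sex_mean + sex_sd * z``.
    """
    if truth.trait_core is None:
        raise ValueError("latent factors must be generated first")
    rng = config.rng(2)
    n = config.n_samples
    samples = truth.latent_factors.columns
    male = rng.random(n) < 0.5

    factors_std = truth.latent_factors.to_numpy()
    if factors_std.size:
        factors_std = factors_std / config.module_factor_sd

    names = [s.name for s in config.trait_specs]
    loadings = pd.DataFrame(0.0, index=names, columns=truth.latent_factors.index)
    if config.causal_topology != "independent" and config.anchored_trait in names \
            and config.n_modules:
        loadings.loc[config.anchored_trait, "M1"] = config.cross_path
    for (trait, module), lam in config.trait_loadings.items():
        if trait in names and 1 <= module <= config.n_modules:
            loadings.loc[trait, f"M{module}"] = lam
    truth.trait_loadings = loadings

    data = {}
    for spec in config.trait_specs:
        if spec.name == config.anchored_trait:
            z = truth.trait_core
        else:
            lam = loadings.loc[spec.name].to_numpy()
            explained = float(np.sum(lam**2))
            if explained >= 1:
                raise ValueError(f"loadings for {spec.name} exceed unit variance")
            z = lam @ factors_std if config.n_modules else np.zeros(n)
            z = z + np.sqrt(1 - explained) * rng.standard_normal(n)
        raw = np.where(
            male,
            spec.male_mean + spec.male_sd * z,
            spec.female_mean + spec.female_sd * z,
        )
        data[spec.name] = raw

    data["age"] = rng.integers(25, 75, size=n).astype(float)
    data["sex"] = np.where(male, "male", "female")
    data["HTM"] = (rng.random(n) < config.htm_prevalence).astype(int)
    data["CM"] = (rng.random(n) < config.cm_prevalence).astype(int)
    data["alcohol"] = np.round(rng.gamma(1.5, 40.0, size=n), 1)  # grams/week

    table = pd.DataFrame(data, index=samples)
    return TraitTable(
        data=table,
        traits=names,
        covariates=["age", "sex", "HTM", "CM", "alcohol"],
    )


def generate_anchored_quartet(
    topology: str,
    n: int = 500,
    anchor_r2: float = 0.10,
    cross_path: float = 0.5,
    maf: float = 0.3,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw one (A, B, M_A, M_B) quartet for edge-orientation studies.

    ``topology`` is "causal" (A -> B with path ``cross_path``), "confounded"
    (A and B load on a shared latent with path ``cross_path`` each), or
    "independent". Anchors are Hardy-Weinberg dosages at ``maf`` explaining
    ``anchor_r2`` of their node's variance; all structural values are on the
    unit-variance scale.
    """
    r = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    m_a = _hwe_dosages(r, maf, n)
    m_b = _hwe_dosages(r, maf, n)
    za, zb = _standardize(m_a), _standardize(m_b)
    a = np.sqrt(anchor_r2)
    b = cross_path
    if topology == "causal":
        A = a * za + np.sqrt(1 - a**2) * r.standard_normal(n)
        B = b * A + a * zb + np.sqrt(max(1 - a**2 - b**2, 1e-9)) * r.standard_normal(n)
    elif topology == "confounded":
        C = r.standard_normal(n)
        res = np.sqrt(max(1 - a**2 - b**2, 1e-9))
        A = a * za + b * C + res * r.standard_normal(n)
        B = a * zb + b * C + res * r.standard_normal(n)
    elif topology == "independent":
        A = a * za + np.sqrt(1 - a**2) * r.standard_normal(n)
        B = a * zb + np.sqrt(1 - a**2) * r.standard_normal(n)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return A, B, m_a, m_b


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GenotypeDataset, TraitTable, GroundTruth]:
    """Run all three generators in order and wire the planted cis effects."""
    expr, truth = generate_expression(config)
    genotypes = generate_genotypes(config, truth)
    apply_cis_effects(expr, genotypes, truth, config)
    traits = generate_traits(config, truth)
    return expr, genotypes, traits, truth
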