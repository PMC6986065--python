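"""Fully labelled synthetic data with the structure the analysis assumes.

The generator emulates the reference study design: 6 tissues (5 fat depots
plus LD muscle), 3 breeds x 4 replicates per tissue (12 samples per depot,
72 in all), log2 intensities with per-gene baselines, gene classes
(muscle-specific, IMF-adipocyte-specific, SC-specific, shared-adipocyte,
background), several probes per gene, a linear-intensity muscle admixture
contaminating the dissected IMF samples, an upward mitoproteome shift in
IMF, and an 8-animal phenotype/metabolite panel driven by a latent marbling
factor.  Every draw is reproducible from a single integer seed and the
ground truth (class labels, clean depot means, contamination fraction,
planted correlations) is returned alongside the data, so parameter-recovery
and filter-soundness tests can audit any pipeline stage.

Contamination mixes linear-scale intensities, not log values: RNA from two
cell populations adds linearly in hybridization signal, so an observed IMF
intensity is (1-alpha) * adipocyte + alpha * muscle before the log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from marbling.io import ExpressionMatrix, GeneSetCollection

FAT_DEPOTS = ("IMF", "SC", "Inter", "Kid", "Omen")
TISSUES = FAT_DEPOTS + ("LD",)
MUSCLE_SET_NAME = "MUSCLE_SYSTEM_PROCESS"

MARBLING_PHENOTYPES = (
    "Biceps_IMF",
    "Chuck_IMF",
    "EyeRound_IMF",
    "Loin_IMF",
    "Oyster_IMF",
    "MSA_MB",
    "AUS_MB",
)
OTHER_PHENOTYPES = (
    "EMA",
    "CWT",
    "P8_fat",
    "Rib_fat",
    "pH",
    "HSCW",
    "Dressing_pct",
    "Hump_height",
)


@dataclass
class SyntheticConfig:
    """Tunable study conditions for the generator.

    Effect sizes and spreads are log2 units.  Class effects are drawn
    uniformly per gene from the given (low, high) range and added to the
    relevant tissue means: muscle-specific genes are elevated in LD,
    IMF-adipocyte-specific in clean IMF, SC-specific in SC, and
    shared-adipocyte genes in all five fat depots.  Breed offsets are drawn
    small relative to depot effects so depot structure dominates breed
    structure, as in the reference data.
    """

    n_genes: int = 5000
    class_proportions: dict = field(
        default_factory=lambda: {
            "muscle": 0.015,
            "imf": 0.02,
            "sc": 0.045,
            "shared": 0.15,
            "background": 0.77,
        }
    )
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    baseline_clip: tuple = (4.0, 17.0)
    muscle_effect: tuple = (2.0, 9.0)
    imf_effect: tuple = (0.8, 2.5)
    sc_effect: tuple = (0.8, 2.5)
    shared_effect: tuple = (0.5, 1.5)
    noise_sd: float = 0.5
    breed_sd: float = 0.1
    breeds: tuple = ("Ang", "Her", "Wag")
    replicates: int = 4
    diet: str = "past"
    kill: str = "5"
    alpha: float = 0.1
    mito_fraction: float = 0.16
    mito_shift: float = 0.3
    mito_classes: tuple = ("background", "shared")
    probe_multiplicity: tuple = (0.30, 0.25, 0.25, 0.20)
    probe_offset_sd: float = 0.3
    annotation_noise: float = 0.0
    n_decoy_sets: int = 5
    decoy_set_size: int = 100
    n_animals: int = 8
    n_metabolites: int = 10
    n_planted_metabolites: int = 1
    phenotype_loading: float = 0.9486832980505138  # sqrt(0.9)
    metabolite_loading: float = 0.9486832980505138  # planted pair r = 0.9

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("contamination fraction alpha must lie in [0, 1]")
        if self.noise_sd < 0 or self.breed_sd < 0 or self.probe_offset_sd < 0:
            raise ValueError("spreads must be nonnegative")
        if abs(sum(self.probe_multiplicity) - 1.0) > 1e-9:
            raise ValueError("probe multiplicity probabilities must sum to 1")

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticConfig":
        """Genome-scale profile: ~14.5k genes, ~34k probes."""
        kwargs = {"n_genes": 14476}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset."""

    genes: pd.DataFrame  # index: symbol; columns: gene_class, mito, effect
    clean_means: pd.DataFrame  # genes x tissues, log2, pre-contamination
    probe_map: pd.Series  # probe -> symbol
    alpha: float
    planted_metabolites: list
    planted_r: float
    config: SyntheticConfig

    def genes_in_class(self, gene_class: str) -> pd.Index:
        return self.genes.index[self.genes["gene_class"] == gene_class]


@dataclass
class SyntheticDataset:
    """Everything one simulated study emits."""

    matrix: ExpressionMatrix  # contaminated, as observed
    clean_matrix: ExpressionMatrix
    truth: SyntheticTruth
    probe_map: pd.Series
    gene_sets: GeneSetCollection
    mito_genes: list
    phenotypes: pd.DataFrame
    metabolites: pd.DataFrame


def _child_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _assign_classes(config: SyntheticConfig, rng) -> np.ndarray:
    names = list(config.class_proportions)
    probs = np.array([config.class_proportions[n] for n in names])
    return rng.choice(names, size=config.n_genes, p=probs)


def _clean_gene_means(config: SyntheticConfig, classes, rng) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-gene clean depot mean profiles, the planted effect, mito flags."""
    n = config.n_genes
    symbols = pd.Index([f"GENE{i:05d}" for i in range(n)], name="gene")
    baseline = np.clip(
        rng.normal(config.baseline_mean, config.baseline_sd, size=n), *config.baseline_clip
    )
    means = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(TISSUES))), index=symbols, columns=list(TISSUES)
    )
    effect = pd.Series(np.zeros(n), index=symbols, name="effect")
    for cls, lohi, targets in (
        ("muscle", config.muscle_effect, ("LD",)),
        ("imf", config.imf_effect, ("IMF",)),
        ("sc", config.sc_effect, ("SC",)),
        ("shared", config.shared_effect, FAT_DEPOTS),
    ):
        mask = classes == cls
        e = rng.uniform(*lohi, size=int(mask.sum()))
        effect[mask] = e
        for t in targets:
            means.loc[mask, t] += e
    # mitoproteome membership with an upward shift in clean IMF
    eligible = np.isin(classes, config.mito_classes)
    n_mito = int(round(config.mito_fraction * n))
    if n_mito > eligible.sum():
        raise ValueError("mito_fraction exceeds the eligible gene classes")
    mito_idx = rng.choice(np.flatnonzero(eligible), size=n_mito, replace=False)
    mito = pd.Series(np.zeros(n, dtype=bool), index=symbols, name="mito")
    mito.iloc[mito_idx] = True
    means.loc[mito, "IMF"] += config.mito_shift
    return means, effect, mito


def _probe_layout(config: SyntheticConfig, symbols: pd.Index, rng) -> tuple[pd.Series, np.ndarray]:
    counts = rng.choice(
        np.arange(1, len(config.probe_multiplicity) + 1),
        size=len(symbols),
        p=np.asarray(config.probe_multiplicity),
    )
    gene_idx = np.repeat(np.arange(len(symbols)), counts)
    probe_ids = []
    for gi, c in zip(np.arange(len(symbols)), counts):
        for j in range(c):
            probe_ids.append(f"A_99_{gi:05d}{j}")
    probe_map = pd.Series(
        symbols[gene_idx].to_numpy(), index=pd.Index(probe_ids, name="probe"), name="gene"
    )
    return probe_map, gene_idx


def generate_clean_tissues(config: SyntheticConfig, seed: int) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the uncontaminated 6-tissue, 3-breed, 4-replicate matrix.

    Each sample value is the gene's clean depot mean plus a per-breed offset
    plus Normal(0, noise_sd) replicate noise, all in log2; each probe adds a
    constant affinity offset shared by every sample (so depot differences
    are probe-invariant).
    """
    rngs = _child_rngs(seed, 4)
    classes = _assign_classes(config, rngs[0])
    means, effect, mito = _clean_gene_means(config, classes, rngs[1])
    symbols = means.index
    probe_map, gene_idx = _probe_layout(config, symbols, rngs[2])

    rng = rngs[3]
    breed_off = rng.normal(0.0, config.breed_sd, size=(config.n_genes, len(config.breeds)))
    sample_ids, meta_rows, cols = [], [], []
    for tissue in TISSUES:
        for bi, breed in enumerate(config.breeds):
            base = means[tissue].to_numpy() + breed_off[:, bi]
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.replicates))
            block = base[:, None] + noise
            for rep in range(config.replicates):
                label = f"{breed}_{config.diet}_{config.kill}_{tissue}"
                sample_ids.append(f"{label}#{rep + 1}")
                meta_rows.append(
                    {"breed": breed, "diet": config.diet, "kill": config.kill, "tissue": tissue}
                )
                cols.append(block[:, rep])
    gene_values = np.column_stack(cols)
    probe_offsets = rng.normal(0.0, config.probe_offset_sd, size=len(probe_map))
    values = gene_values[gene_idx] + probe_offsets[:, None]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_map.index, columns=sample_ids),
        pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample")),
    )
    genes = pd.DataFrame({"gene_class": classes, "mito": mito.to_numpy(), "effect": effect.to_numpy()}, index=symbols)
    truth = SyntheticTruth(
        genes=genes,
        clean_means=means,
        probe_map=probe_map,
        alpha=0.0,
        planted_metabolites=[],
        planted_r=float("nan"),
        config=config,
    )
    return matrix, truth


def admix_contamination(imf_clean, ld, alpha: float):
    """Mix clean IMF with LD muscle at linear-intensity fraction ``alpha``.

    Per value: log2((1-alpha) * 2**clean + alpha * 2**ld).  alpha = 0
    returns the clean input unchanged and alpha = 1 returns the LD input.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    clean = np.asarray(imf_clean, dtype=float)
    muscle = np.asarray(ld, dtype=float)
    if clean.shape != muscle.shape:
        raise ValueError("IMF and LD arrays must have matching shapes")
    if alpha == 0.0:
        mixed = clean.copy()
    elif alpha == 1.0:
        mixed = muscle.copy()
    else:
        mixed = np.log2((1.0 - alpha) * np.exp2(clean) + alpha * np.exp2(muscle))
    if isinstance(imf_clean, pd.DataFrame):
        return pd.DataFrame(mixed, index=imf_clean.index, columns=imf_clean.columns)
    return mixed


def _contaminate_matrix(matrix: ExpressionMatrix, alpha: float) -> ExpressionMatrix:
    """Replace each IMF sample by its admixture with the matched LD sample.

    IMF replicate k of a breed is paired with LD replicate k of the same
    breed, mimicking per-animal carry-over of muscle into the dissection.
    """
    values = matrix.values.copy()
    for breed in matrix.samples["breed"].unique():
        sel = matrix.samples["breed"] == breed
        imf_cols = matrix.samples.index[sel & (matrix.samples["tissue"] == "IMF")]
        ld_cols = matrix.samples.index[sel & (matrix.samples["tissue"] == "LD")]
        if len(imf_cols) != len(ld_cols):
            raise ValueError("IMF and LD replicate counts differ within a breed")
        mixed = admix_contamination(
            matrix.values[imf_cols].to_numpy(), matrix.values[ld_cols].to_numpy(), alpha
        )
        values[imf_cols] = mixed
    return ExpressionMatrix(values, matrix.samples)


def generate_annotations(
    truth: SyntheticTruth, rng=None, noise: float | None = None
) -> tuple[GeneSetCollection, list]:
    """Annotation artifacts: a muscle gene set, decoy sets, the mito list.

    The "muscle system process"-like set is the muscle-class genes; with
    annotation ``noise`` f, a fraction f of true members is replaced by
    random non-members (Jaccard with the class is then ~(1-f)/(1+f)).
    Decoy sets are uniform random draws from all genes.  The mitoproteome
    list is exactly the genes carrying the planted mito shift.
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(0)
    if noise is None:
        noise = cfg.annotation_noise
    symbols = truth.genes.index
    muscle = list(truth.genes_in_class("muscle"))
    if noise > 0:
        n_swap = int(round(noise * len(muscle)))
        drop = set(rng.choice(muscle, size=n_swap, replace=False))
        pool = symbols[~symbols.isin(muscle)]
        add = rng.choice(pool, size=n_swap, replace=False)
        muscle = sorted((set(muscle) - drop) | set(add))
    sets = {MUSCLE_SET_NAME: frozenset(muscle)}
    for d in range(cfg.n_decoy_sets):
        members = rng.choice(symbols, size=min(cfg.decoy_set_size, len(symbols)), replace=False)
        sets[f"DECOY_SET_{d + 1}"] = frozenset(members)
    mito_genes = sorted(truth.genes.index[truth.genes["mito"]])
    return GeneSetCollection(sets, background=frozenset(symbols)), mito_genes


def generate_phenotypes_metabolites(
    config: SyntheticConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the 8-animal phenotype and plasma-metabolite tables.

    A latent marbling factor drives the 7 marbling phenotypes (loading
    ``phenotype_loading``) and the planted metabolites (loading
    ``metabolite_loading``); their population correlation is the product of
    the loadings (0.9 by default).  Non-marbling phenotypes and unplanted
    metabolites are independent standard normal noise.
    """
    rng = np.random.default_rng(seed)
    n = config.n_animals
    animals = pd.Index([f"Animal{i + 1}" for i in range(n)], name="animal")
    latent = rng.normal(size=n)

    a = config.phenotype_loading
    pheno = {}
    for name in MARBLING_PHENOTYPES:
        pheno[name] = a * latent + np.sqrt(1 - a**2) * rng.normal(size=n)
    for name in OTHER_PHENOTYPES:
        pheno[name] = rng.normal(size=n)
    phenotypes = pd.DataFrame(pheno, index=animals)

    b = config.metabolite_loading
    planted = [f"Met{i + 1:02d}" for i in range(config.n_planted_metabolites)]
    metab = {}
    for i in range(config.n_metabolites):
        name = f"Met{i + 1:02d}"
        if name in planted:
            metab[name] = b * latent + np.sqrt(1 - b**2) * rng.normal(size=n)
        else:
            metab[name] = rng.normal(size=n)
    metabolites = pd.DataFrame(metab, index=animals)
    truth = {"planted_metabolites": planted, "planted_r": a * b, "latent": latent}
    return phenotypes, metabolites, truth


def generate(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Run the whole generator: matrices, truth, annotations, phenotypes."""
    if config is None:
        config = SyntheticConfig()
    ss = np.random.SeedSequence(seed).spawn(3)
    clean, truth = generate_clean_tissues(config, seed)
    contaminated = _contaminate_matrix(clean, config.alpha)
    gene_sets, mito_genes = generate_annotations(
        truth, rng=np.random.default_rng(ss[1])
    )
    pheno, metab, ptruth = generate_phenotypes_metabolites(
        config, np.random.default_rng(ss[2]).integers(2**31)
    )
    truth.alpha = config.alpha
    truth.planted_metabolites = ptruth["planted_metabolites"]
    truth.planted_r = ptruth["planted_r"]
    return SyntheticDataset(
        matrix=contaminated,
        clean_matrix=clean,
        truth=truth,
        probe_map=truth.probe_map,
        gene_sets=gene_sets,
        mito_genes=mito_genes,
        phenotypes=pheno,
        metabolites=metab,
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


def config_from_dict(data: dict) -> SyntheticConfig:
    cfg = dict(data)
    for key in ("baseline_clip", "muscle_effect", "imf_effect", "sc_effect",
                "shared_effect", "breeds", "mito_classes", "probe_multiplicity"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return SyntheticConfig(**cfg)
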