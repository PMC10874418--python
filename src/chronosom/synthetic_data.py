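"""Synthetic age-structured case/control cohorts with planted gene modules.

The generator emulates the statistical structure the portrait/perturbation
analysis assumes: a control arm spanning the whole lifespan (ages sampled
from the nine-bin mixture of the reference cohort design), disease arms
restricted to post-onset ages (>= 18 y), co-expressed gene modules whose
baseline expression follows smooth closed-form age trajectories, per-disease
divergences that switch on at a planted perturbation age tau, sample-level
nuisance offsets (batch, sex, pH, PMI) and i.i.d. Gaussian noise, all in
log2 units.

Module trajectories are logistic (or Gaussian-peak) functions of age rather
than GP draws so that every planted value has a closed form the tests can
evaluate independently.  The disease divergence is a half-sigmoid ramp

    d(a) = sign * amplitude * (2 / (1 + exp(-(a - tau) / rise)) - 1),  a > tau

and exactly zero for a <= tau, so case and control trajectories coincide
before the perturbation age and diverge smoothly after it — the continuity
assumption of the GP branch-point model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chronosom.preprocess import AGE_GROUP_LABELS, AGE_GROUPS

DISEASES = ("SCZ", "BD", "MDD")

#: Reference cohort design: number of samples per age bin for each group.
#: Bins follow AGE_GROUPS / AGE_GROUP_LABELS order.  Control counts weight
#: the control-arm age sampler; disease arms are sampled uniformly on
#: [18, 85] (no pre-onset cases).
REFERENCE_COHORT_COUNTS = pd.DataFrame(
    {
        "CNTRL": [26, 12, 15, 37, 59, 6, 56, 33, 9],
        "SCZ": [0, 0, 0, 0, 25, 59, 25, 33, 3],
        "BD": [0, 0, 0, 0, 16, 34, 21, 2, 0],
        "MDD": [0, 0, 0, 0, 14, 18, 13, 1, 0],
    },
    index=AGE_GROUP_LABELS,
)

#: Ramp rise scale in years (half-sigmoid divergence after tau).
RAMP_RISE_YEARS = 5.0


@dataclass(frozen=True)
class ModuleTrajectory:
    """Closed-form baseline age trajectory of one module (log2 units).

    family: 'constant', 'logistic-decline', 'logistic-rise' or 'peak'.
    For the logistic families the value moves between +amplitude/2 and
    -amplitude/2 with midpoint ``mid`` (years) and slope scale ``scale``
    (years); 'peak' is a Gaussian bump of height ``amplitude`` centered at
    ``mid`` with width ``scale``.
    """

    family: str
    amplitude: float = 2.0
    mid: float = 40.0
    scale: float = 10.0

    def __call__(self, ages: np.ndarray | float) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        if self.family == "constant":
            return np.zeros_like(a)
        if self.family == "logistic-decline":
            return self.amplitude * (0.5 - 1.0 / (1.0 + np.exp(-(a - self.mid) / self.scale)))
        if self.family == "logistic-rise":
            return self.amplitude * (1.0 / (1.0 + np.exp(-(a - self.mid) / self.scale)) - 0.5)
        if self.family == "peak":
            return self.amplitude * np.exp(-((a - self.mid) ** 2) / (2.0 * self.scale**2))
        raise ValueError(f"unknown trajectory family {self.family!r}")


@dataclass(frozen=True)
class PlantedPerturbation:
    """One planted (module, disease) divergence: onset age and amplitude."""

    tau: float  # years
    amplitude: float  # log2 units (asymptotic |divergence|)
    sign: int = 1  # +1 over-, -1 under-expression in disease


def divergence_ramp(
    ages: np.ndarray | float, tau: float, amplitude: float, sign: int = 1,
    rise: float = RAMP_RISE_YEARS,
) -> np.ndarray:
    """Half-sigmoid disease-minus-control divergence; exactly 0 for age <= tau."""
    a = np.asarray(ages, dtype=float)
    ramp = sign * amplitude * (2.0 / (1.0 + np.exp(-(a - tau) / rise)) - 1.0)
    return np.where(a > tau, ramp, 0.0)


def _default_trajectories(n_modules: int) -> list[ModuleTrajectory]:
    """Distinct biologically-flavoured baselines for the planted modules.

    The defaults mimic the canonical aging-brain programmes: early
    neurodevelopmental decline, adolescent metabolic rise, myelination
    peaking at maturity, midlife synaptic decline, late glial/immune rise.
    Midpoints and signs are spread so module profiles are mutually
    distinguishable, as real co-expression programmes are.
    """
    prototypes = [
        ModuleTrajectory("logistic-decline", amplitude=2.0, mid=12.0, scale=5.0),
        ModuleTrajectory("logistic-rise", amplitude=2.0, mid=20.0, scale=6.0),
        ModuleTrajectory("peak", amplitude=2.0, mid=30.0, scale=12.0),
        ModuleTrajectory("logistic-decline", amplitude=2.0, mid=45.0, scale=12.0),
        ModuleTrajectory("logistic-rise", amplitude=2.0, mid=55.0, scale=12.0),
    ]
    out = []
    for m in range(n_modules):
        proto = prototypes[m % len(prototypes)]
        shift = 8.0 * (m // len(prototypes))  # stagger extra modules
        out.append(
            ModuleTrajectory(proto.family, proto.amplitude, proto.mid + shift, proto.scale)
        )
    return out


def _default_perturbations(n_modules: int, noise_sd: float) -> dict[tuple[int, str], PlantedPerturbation]:
    """One planted perturbation per module, cycling diseases, taus and signs."""
    taus = [5.0, 30.0, 60.0]
    table: dict[tuple[int, str], PlantedPerturbation] = {}
    for m in range(n_modules):
        disease = DISEASES[m % len(DISEASES)]
        tau = taus[m % len(taus)]
        sign = 1 if m % 2 == 0 else -1
        table[(m, disease)] = PlantedPerturbation(tau=tau, amplitude=3.0 * noise_sd, sign=sign)
    return table


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a desk-scale cohort: 2000 genes, 5 planted modules of 100
    genes, 60 controls spanning 0-100 y and 30 cases per disease on
    [18, 85] y, noise sd 0.5 log2 units and nuisance effects of realistic
    magnitude relative to the module amplitude of 2 log2 units.
    """

    n_genes: int = 2000
    n_modules: int = 5
    genes_per_module: int = 100
    n_control: int = 60
    n_per_disease: int = 30
    diseases: tuple[str, ...] = DISEASES
    trajectories: list[ModuleTrajectory] | None = None
    perturbations: dict[tuple[int, str], PlantedPerturbation] | None = None
    noise_sd: float = 0.5
    n_batches: int = 4
    batch_effect: float = 0.4  # log2 units between adjacent batch levels
    sex_effect: float = 0.2  # log2 units M vs F
    ph_effect: float = 0.3  # log2 units per pH unit from 6.5
    pmi_effect: float = 0.01  # log2 units per hour of PMI from the mean
    disease_age_range: tuple[float, float] = (18.0, 85.0)
    seed: int = 0

    def resolved_trajectories(self) -> list[ModuleTrajectory]:
        if self.trajectories is not None:
            if len(self.trajectories) != self.n_modules:
                raise ValueError("need one trajectory per module")
            return list(self.trajectories)
        return _default_trajectories(self.n_modules)

    def resolved_perturbations(self) -> dict[tuple[int, str], PlantedPerturbation]:
        if self.perturbations is not None:
            return dict(self.perturbations)
        return _default_perturbations(self.n_modules, self.noise_sd)

    def validate(self) -> None:
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError("n_modules * genes_per_module exceeds n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for (m, dis), pert in self.resolved_perturbations().items():
            if not 0 <= m < self.n_modules:
                raise ValueError(f"perturbation references unknown module {m}")
            if dis not in self.diseases:
                raise ValueError(f"perturbation references unknown disease {dis!r}")
            if not 0.0 <= pert.tau <= 100.0:
                raise ValueError(f"tau {pert.tau} outside [0, 100] years")


@dataclass
class SyntheticTruth:
    """Planted ground truth: module memberships, perturbations, nuisance."""

    modules: dict[str, list[str]]  # module id -> member gene ids
    background_genes: list[str]
    trajectories: dict[str, ModuleTrajectory]
    perturbations: dict[tuple[str, str], PlantedPerturbation]  # (module, disease)
    nuisance_offsets: pd.Series  # per-sample offset applied to every gene

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.modules.values():
            out.extend(genes)
        out.extend(self.background_genes)
        return out

    def module_of(self, gene: str) -> str | None:
        for mod, genes in self.modules.items():
            if gene in genes:
                return mod
        return None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modules": self.modules,
            "background_genes": self.background_genes,
            "trajectories": {
                m: {"family": t.family, "amplitude": t.amplitude, "mid": t.mid, "scale": t.scale}
                for m, t in self.trajectories.items()
            },
            "perturbations": [
                {
                    "module": m,
                    "disease": d,
                    "tau": p.tau,
                    "amplitude": p.amplitude,
                    "sign": p.sign,
                }
                for (m, d), p in self.perturbations.items()
            ],
            "nuisance_offsets": {k: float(v) for k, v in self.nuisance_offsets.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            modules=payload["modules"],
            background_genes=payload["background_genes"],
            trajectories={
                m: ModuleTrajectory(**t) for m, t in payload["trajectories"].items()
            },
            perturbations={
                (rec["module"], rec["disease"]): PlantedPerturbation(
                    rec["tau"], rec["amplitude"], rec["sign"]
                )
                for rec in payload["perturbations"]
            },
            nuisance_offsets=pd.Series(payload["nuisance_offsets"]),
        )


def _sample_control_ages(n: int, rng: np.random.Generator) -> np.ndarray:
    """Ages from the nine-bin mixture weighted by the reference control counts."""
    counts = REFERENCE_COHORT_COUNTS["CNTRL"].to_numpy(float)
    probs = counts / counts.sum()
    bins = rng.choice(len(AGE_GROUPS), size=n, p=probs)
    lows = np.array([lo for lo, _ in AGE_GROUPS])[bins]
    highs = np.array([hi for _, hi in AGE_GROUPS])[bins]
    ages = lows + rng.uniform(0.0, 1.0, size=n) * (highs - lows)
    return np.maximum(ages, 0.01)  # keep ages inside the (0, 100] bin support


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate (expression matrix, sample metadata, planted truth).

    Expression of gene g in sample s:
    module baseline trajectory at age(s) [0 for background genes]
    + disease divergence ramp (if s belongs to a perturbed disease arm)
    + sample nuisance offset + N(0, noise_sd).  Identical seed, identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trajectories = config.resolved_trajectories()
    perturbations = config.resolved_perturbations()

    # --- samples ---------------------------------------------------------
    groups = ["CNTRL"] * config.n_control
    for dis in config.diseases:
        groups += [dis] * config.n_per_disease
    n_samples = len(groups)
    ages = np.empty(n_samples)
    ages[: config.n_control] = _sample_control_ages(config.n_control, rng)
    lo, hi = config.disease_age_range
    ages[config.n_control:] = rng.uniform(lo, hi, size=n_samples - config.n_control)

    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    sex = rng.choice(["M", "F"], size=n_samples)
    ph = rng.normal(6.5, 0.25, size=n_samples)
    pmi = rng.uniform(5.0, 40.0, size=n_samples)
    batch = np.array(
        [f"batch{(i % config.n_batches) + 1}" for i in range(n_samples)]
    )

    meta = pd.DataFrame(
        {
            "diagnosis": groups,
            "age": ages,
            "sex": sex,
            "ph": ph,
            "pmi": pmi,
            "batch": batch,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- sample-level nuisance offsets (same for every gene) -------------
    batch_idx = np.array([int(b[5:]) - 1 for b in batch], dtype=float)
    batch_idx -= (config.n_batches - 1) / 2.0
    offsets = (
        config.batch_effect * batch_idx
        + config.sex_effect * np.where(sex == "M", 0.5, -0.5)
        + config.ph_effect * (ph - 6.5)
        + config.pmi_effect * (pmi - 22.5)
    )
    nuisance = pd.Series(offsets, index=meta.index, name="nuisance_offset")

    # --- genes ------------------------------------------------------------
    module_ids = [f"M{m + 1}" for m in range(config.n_modules)]
    gene_ids: list[str] = []
    modules: dict[str, list[str]] = {}
    for m, mod in enumerate(module_ids):
        genes = [f"{mod}_G{g + 1:03d}" for g in range(config.genes_per_module)]
        modules[mod] = genes
        gene_ids.extend(genes)
    n_bg = config.n_genes - len(gene_ids)
    background = [f"BG_G{g + 1:04d}" for g in range(n_bg)]
    gene_ids.extend(background)

    # --- expression -------------------------------------------------------
    values = np.zeros((config.n_genes, n_samples))
    for m, mod in enumerate(module_ids):
        base = trajectories[m](ages)
        row = base.copy()
        for dis in config.diseases:
            pert = perturbations.get((m, dis))
            if pert is None:
                continue
            in_arm = np.array(groups) == dis
            row[in_arm] += divergence_ramp(
                ages[in_arm], pert.tau, pert.amplitude, pert.sign
            )
        sl = slice(m * config.genes_per_module, (m + 1) * config.genes_per_module)
        values[sl, :] = row[np.newaxis, :]
    # background genes stay at constant baseline 0

    values += offsets[np.newaxis, :]
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    X = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=meta.index)

    truth = SyntheticTruth(
        modules=modules,
        background_genes=background,
        trajectories={mod: trajectories[m] for m, mod in enumerate(module_ids)},
        perturbations={
            (module_ids[m], dis): pert for (m, dis), pert in perturbations.items()
        },
        nuisance_offsets=nuisance,
    )
    return X, meta, truth


def generate_genesets(
    truth: SyntheticTruth, extra_random_sets: int = 0, seed: int = 0,
    decoy_size: int | None = None,
) -> "GeneSetCollection":
    """Gene sets: one per planted module plus random decoys from the background."""
    from chronosom.annotate import GeneSetCollection

    if not truth.modules:
        raise ValueError("truth has no planted modules")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for mod, genes in truth.modules.items():
        sets[f"SET_{mod}"] = list(genes)
        descriptions[f"SET_{mod}"] = f"planted module {mod}"
    if extra_random_sets:
        rng = np.random.default_rng(seed)
        pool = list(truth.background_genes)
        size = decoy_size or len(next(iter(truth.modules.values())))
        if size > len(pool):
            raise ValueError("decoy set size exceeds background gene count")
        for i in range(extra_random_sets):
            picked = rng.choice(pool, size=size, replace=False)
            name = f"DECOY_{i + 1:02d}"
            sets[name] = sorted(picked.tolist())
            descriptions[name] = "random background decoy set"
    return GeneSetCollection(sets, descriptions)


def generate_eqtl_table(
    truth: SyntheticTruth,
    n_tissues: int = 47,
    enriched_pairs: list[tuple[str, str]] | None = None,
    baseline_rate: float = 0.1,
    enriched_rate: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary gene x tissue eQTL flags.

    Genes of each enriched (module, tissue) pair are flagged at
    ``enriched_rate``; everything else at ``baseline_rate``.  The first two
    tissue names mimic the brain/blood tissues of interest; the rest are
    generic.
    """
    if not 0.0 <= baseline_rate <= 1.0:
        raise ValueError("baseline_rate must be in [0, 1]")
    if not 0.0 <= enriched_rate <= 1.0:
        raise ValueError("enriched_rate must be in [0, 1]")
    tissues = ["Brain_Cortex", "Whole_Blood"] + [
        f"Tissue{i + 1:02d}" for i in range(max(0, n_tissues - 2))
    ]
    tissues = tissues[:n_tissues]
    rng = np.random.default_rng(seed)
    genes = truth.all_genes
    flags = (rng.uniform(size=(len(genes), n_tissues)) < baseline_rate).astype(int)
    table = pd.DataFrame(flags, index=pd.Index(genes, name="gene_id"), columns=tissues)
    for mod, tissue in enriched_pairs or []:
        if mod not in truth.modules:
            raise ValueError(f"unknown module id {mod!r}")
        if tissue not in table.columns:
            raise ValueError(f"unknown tissue {tissue!r}")
        members = truth.modules[mod]
        table.loc[members, tissue] = (
            rng.uniform(size=len(members)) < enriched_rate
        ).astype(int)
    return table
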