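"""Synthetic expression studies with planted coexpression structure.

The generative model is a latent-factor model: each planted module m has one
standard-normal factor f_m per sample, and a member gene g is

    x_g = baseline + group_shift[group(sample)] + loading_m * f_m + noise_sd * eps

with iid Gaussian noise.  Background genes are baseline + noise only.

The impairment trait is a noisy linear combination of the module factors

    z = sum_m trait_effect_m * f_m + sqrt(1 - sum_m trait_effect_m**2) * eta

with independent standard-normal eta, so that in population
cor(z, f_m) = trait_effect_m exactly (factors are independent).  This
requires sum_m trait_effect_m**2 <= 1, which is validated.  The stored
clinical score is an affine rescaling of z onto the instrument's range
(GCR 1-9 with higher = more impaired, or MMSE 0-30 with lower = more
impaired); clipping to the legal range affects < 0.3% of draws and is
negligible for correlation targets.

All randomness flows from ``design.seed`` through a numpy SeedSequence
spawned into named substreams (factors, noise, trait, cpe, presence), so a
design is byte-reproducible and adding e.g. presence calls does not perturb
the expression draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .study import ExpressionStudy
from . import io as _io

BASELINE = 8.0  # log-scale intensity offset; cosmetic only

#: substream order under the design's SeedSequence; fixed for reproducibility
_STREAMS = ("factors", "noise", "trait", "cpe", "presence", "shared")


@dataclass
class ModuleSpec:
    """One planted coexpression module."""

    module_id: str
    size: int
    factor_loading: float = 0.9
    trait_effect: float = 0.0
    group_shifts: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"module {self.module_id}: size must be >= 1")
        if not -1.0 <= self.factor_loading <= 1.0:
            raise ValueError(f"module {self.module_id}: |factor_loading| must be <= 1")
        if not -1.0 <= self.trait_effect <= 1.0:
            raise ValueError(f"module {self.module_id}: |trait_effect| must be <= 1")


@dataclass
class SyntheticDesign:
    """Full description of one synthetic study; the seed determines everything."""

    modules: list[ModuleSpec] = field(default_factory=list)
    n_background_genes: int = 0
    samples_per_group: Mapping[str, int] = field(default_factory=lambda: {"A": 10})
    noise_sd: float = 1.0
    probes_per_gene: int = 1
    absent_fraction: float | None = None
    trait: str = "GCR"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.absent_fraction is not None and not 0.0 <= self.absent_fraction <= 1.0:
            raise ValueError("absent_fraction must lie in [0, 1]")
        if self.trait not in ("GCR", "MMSE"):
            raise ValueError("trait must be 'GCR' or 'MMSE'")
        effect_ss = sum(m.trait_effect**2 for m in self.modules)
        if effect_ss > 1.0 + 1e-12:
            raise ValueError(
                "sum of squared trait_effects exceeds 1; the trait cannot "
                "simultaneously achieve these correlations"
            )
        groups = set(self.samples_per_group)
        for m in self.modules:
            if m.group_shifts is None:
                continue
            if set(m.group_shifts) != groups:
                raise ValueError(
                    f"module {m.module_id}: group_shifts must have one entry per "
                    f"declared group {sorted(groups)}"
                )
            for g, shift in m.group_shifts.items():
                if self.samples_per_group[g] == 0 and shift != 0:
                    raise ValueError(
                        f"module {m.module_id}: nonzero shift for empty group {g!r}"
                    )

    @property
    def n_genes(self) -> int:
        return sum(m.size for m in self.modules) + self.n_background_genes

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_group.values())


@dataclass
class StudyTruth:
    """Ground truth accompanying a generated study (for tests/validation)."""

    labels: pd.Series  # gene -> module_id or "background"
    factors: pd.DataFrame  # modules x samples latent factors
    impairment: pd.Series  # standardized latent impairment per sample


def gene_names(design: SyntheticDesign) -> list[str]:
    """Deterministic gene universe of a design: module genes then background."""
    names: list[str] = []
    for m in design.modules:
        names.extend(f"{m.module_id}_{i:04d}" for i in range(m.size))
    names.extend(f"BG_{i:05d}" for i in range(design.n_background_genes))
    return names


def _sample_table(design: SyntheticDesign) -> pd.DataFrame:
    rows = []
    i = 0
    for group, n in design.samples_per_group.items():
        for _ in range(n):
            rows.append({"sample_id": f"S{i:04d}", "group": group})
            i += 1
    table = pd.DataFrame(rows).set_index("sample_id")
    table.index.name = None  # axis names are supplied at write time
    return table


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def generate_study_truth(design: SyntheticDesign) -> tuple[ExpressionStudy, StudyTruth]:
    """Generate a study together with its ground truth."""
    rngs = _streams(design.seed)
    pheno = _sample_table(design)
    n = len(pheno)
    if n == 0:
        raise ValueError("design has no samples")
    genes = gene_names(design)

    n_modules = len(design.modules)
    factors = rngs["factors"].standard_normal((n_modules, n))

    # latent impairment: exact population correlation trait_effect_m per factor
    effects = np.array([m.trait_effect for m in design.modules])
    resid_sd = math.sqrt(max(0.0, 1.0 - float(effects @ effects)))
    z = effects @ factors + resid_sd * rngs["trait"].standard_normal(n) if n_modules else (
        rngs["trait"].standard_normal(n)
    )

    expr = np.empty((len(genes), n))
    labels = []
    row = 0
    group_vector = pheno["group"].to_numpy()
    noise = rngs["noise"]
    for mi, m in enumerate(design.modules):
        shift = np.zeros(n)
        if m.group_shifts is not None:
            shift = np.array([m.group_shifts[g] for g in group_vector], dtype=float)
        block = (
            BASELINE
            + shift
            + m.factor_loading * factors[mi]
            + design.noise_sd * noise.standard_normal((m.size, n))
        )
        expr[row : row + m.size] = block
        labels.extend([m.module_id] * m.size)
        row += m.size
    if design.n_background_genes:
        expr[row:] = BASELINE + design.noise_sd * noise.standard_normal(
            (design.n_background_genes, n)
        )
        labels.extend(["background"] * design.n_background_genes)

    pheno = _attach_traits(design, pheno, z, rngs["cpe"])

    expression = pd.DataFrame(expr, index=genes, columns=pheno.index)
    expression, probe_to_gene = _expand_probes(expression, design.probes_per_gene)

    presence = None
    if design.absent_fraction is not None:
        present = rngs["presence"].random(expression.shape) >= design.absent_fraction
        presence = pd.DataFrame(
            present, index=expression.index, columns=expression.columns
        )

    study = ExpressionStudy(
        expression=expression,
        phenotypes=pheno,
        presence=presence,
        probe_to_gene=probe_to_gene,
    )
    truth = StudyTruth(
        labels=pd.Series(labels, index=genes, name="module"),
        factors=pd.DataFrame(
            factors, index=[m.module_id for m in design.modules], columns=pheno.index
        ),
        impairment=pd.Series(z, index=pheno.index, name="impairment"),
    )
    return study, truth


def generate_study(design: SyntheticDesign) -> ExpressionStudy:
    """Generate a synthetic expression study (see module docstring)."""
    return generate_study_truth(design)[0]


def _attach_traits(
    design: SyntheticDesign,
    pheno: pd.DataFrame,
    z: np.ndarray,
    rng_cpe: np.random.Generator,
) -> pd.DataFrame:
    pheno = pheno.copy()
    if design.trait == "GCR":
        # GCR 1-9, higher = more impaired; affine map of z, clipped (rare)
        gcr = np.clip(5.0 + (4.0 / 3.0) * z, 1.0, 9.0)
        cpe = np.clip(2.0 + 0.8 * rng_cpe.standard_normal(len(pheno)), 0.0, None)
        pheno["GCR"] = gcr
        pheno["CPE"] = cpe
        # seronegative controls (group A) have no impairment/regimen scores
        mask_a = pheno["group"].astype(str) == "A"
        pheno.loc[mask_a, ["GCR", "CPE"]] = np.nan
    else:
        # MMSE 0-30, lower = more impaired
        pheno["MMSE"] = np.clip(15.0 - 4.0 * z, 0.0, 30.0)
    return pheno


def _expand_probes(
    expression: pd.DataFrame, probes_per_gene: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Duplicate each gene into probes with deterministic per-probe offsets.

    Probe 0 carries the highest mean so max-mean collapsing recovers the
    original gene row exactly (up to the offset).
    """
    if probes_per_gene == 1:
        probe_to_gene = pd.Series(
            expression.index, index=expression.index, name="gene"
        )
        return expression, probe_to_gene
    rows = []
    probes = []
    mapping = {}
    for gene in expression.index:
        base = expression.loc[gene].to_numpy()
        for k in range(probes_per_gene):
            probe = f"{gene}.p{k}"
            rows.append(base - 0.5 * k)
            probes.append(probe)
            mapping[probe] = gene
    out = pd.DataFrame(rows, index=probes, columns=expression.columns)
    return out, pd.Series(mapping, name="gene")


def generate_paired_disease_studies(
    design_hiv: SyntheticDesign,
    design_ad: SyntheticDesign,
    shared_impairment_genes: Iterable[str] | Mapping[str, int],
    shared_effect: float,
) -> tuple[ExpressionStudy, ExpressionStudy]:
    """Two-disease design sharing a planted impairment-gene set.

    ``shared_impairment_genes`` may be a mapping gene -> direction (+1 up with
    impairment, -1 down) or a plain iterable (all +1).  Each shared gene g is
    regenerated in both studies as

        x_g = baseline + dir_g * shared_effect * z + sqrt(1-shared_effect^2) * eps

    where z is that study's standardized latent impairment, so in population
    cor(x_g, impairment) = dir_g * shared_effect in both diseases.  Other
    genes are untouched (trait-independent unless their module has a
    trait_effect).  design_hiv must use the GCR trait and design_ad the MMSE
    trait.
    """
    if not 0.0 <= shared_effect <= 1.0:
        raise ValueError("shared_effect must lie in [0, 1]")
    if design_hiv.trait != "GCR" or design_ad.trait != "MMSE":
        raise ValueError("design_hiv must use trait GCR and design_ad trait MMSE")
    if isinstance(shared_impairment_genes, Mapping):
        directions = {g: int(d) for g, d in shared_impairment_genes.items()}
    else:
        directions = {g: 1 for g in shared_impairment_genes}
    if any(d not in (-1, 1) for d in directions.values()):
        raise ValueError("directions must be +1 or -1")

    universe_hiv = set(gene_names(design_hiv))
    universe_ad = set(gene_names(design_ad))
    if not universe_hiv & universe_ad:
        raise ValueError("the two designs have disjoint gene universes")
    missing = [g for g in directions if g not in universe_hiv or g not in universe_ad]
    if missing:
        raise ValueError(
            f"shared genes absent from a design's universe: {sorted(missing)[:5]}"
        )

    out = []
    for design in (design_hiv, design_ad):
        study, truth = generate_study_truth(design)
        if directions:
            rng = _streams(design.seed)["shared"]
            z = truth.impairment.to_numpy()
            zs = (z - z.mean()) / z.std()
            resid = math.sqrt(1.0 - shared_effect**2)
            for gene in sorted(directions):
                eps = rng.standard_normal(len(zs))
                profile = (
                    BASELINE
                    + directions[gene] * shared_effect * zs
                    + resid * eps
                )
                _overwrite_gene(study, gene, profile)
        out.append(study)
    return out[0], out[1]


def _overwrite_gene(study: ExpressionStudy, gene: str, profile: np.ndarray) -> None:
    if study.probe_to_gene is not None:
        probes = study.probe_to_gene.index[study.probe_to_gene == gene]
    else:
        probes = [gene]
    for k, probe in enumerate(probes):
        study.expression.loc[probe] = profile - 0.5 * k


def write_fixtures(study: ExpressionStudy, directory) -> dict:
    """Write a study as plain-text fixtures; see :mod:`coexnet.io`."""
    return _io.write_study(study, directory)
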