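"""Forward models with planted ground truth.

Three generators produce every input the downstream pipeline consumes:

* a single-turn TCA atom-routing simulator for citrate isotopologues under
  uniformly labelled glucose, uniformly labelled glutamine, or 13C
  bicarbonate tracers, with per-carbon bookkeeping of the six citrate
  positions;
* a GC-MS-style isotopologue intensity-table generator (natural-abundance
  convolution, internal-standard channel, multiplicative + additive noise);
* replicate expression-experiment and binary gene-call generators for the
  transcriptome selection and mutual-exclusivity stages.

Atom bookkeeping
----------------
Citrate's six carbons are tracked positionally: positions 0-1 derive from
acetyl-CoA, positions 2-5 from oxaloacetate (OAA); position 5 is the OAA
carboxyl that derives from the carboxylation CO2 (the carbon added when
alpha-ketoglutarate is reductively carboxylated, and the carbon the C5
GC-MS fragment loses).  Routing pathways then map onto label patterns:

* oxidative glucose route: labelled acetyl-CoA -> positions {0, 1} (m+2);
* oxidative glutamine route: OAA m+4 -> positions {2, 3, 4, 5} (m+4 full,
  m+3 in the C5 fragment which lacks position 5);
* reductive glutamine route: alpha-KG m+5 -> positions {0, 1, 2, 3, 4}
  (m+5 in both full and C5 fragments; the CO2-derived position 5 is cold);
* pyruvate-carboxylase route under glucose: OAA from labelled pyruvate +
  cold CO2 -> positions {2, 3, 4} (m+3);
* bicarbonate fixation: position {5} only (m+1 full, m+0 in C5).

Only one TCA turn is modelled; multi-turn scrambling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mid import MIDVector, NATURAL_13C, convolve_envelope, natural_abundance_envelope

N_CITRATE_CARBONS = 6
#: Citrate positions contributed by acetyl-CoA vs oxaloacetate.
ACETYL_POSITIONS = (0, 1)
OAA_POSITIONS = (2, 3, 4, 5)
#: The carboxylation-derived OAA carboxyl (the carbon the C5 fragment loses).
CARBOXYLATION_POSITION = 5

#: Metabolite name of the spiked internal standard.
INTERNAL_STANDARD = "cinnamic_acid"
INTERNAL_STANDARD_MZ = 131


class Tracer(str, Enum):
    """Labelling substrate of a pulse experiment."""

    U13C6_GLUCOSE = "U13C6_glucose"
    U13C5_GLUTAMINE = "U13C5_glutamine"
    C13_BICARBONATE = "C13_bicarbonate"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class TracerSpec:
    """A tracer plus its pulse duration (metadata only).

    Default durations follow common pulse protocols: 7 min for glucose,
    15 min for glutamine, 20 min for bicarbonate.
    """

    name: Tracer
    labeling_minutes: float = 15.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", Tracer(self.name))
        if self.labeling_minutes <= 0:
            raise ValueError("labeling_minutes must be positive")


def _as_tracer(tracer) -> Tracer:
    if isinstance(tracer, TracerSpec):
        return tracer.name
    return Tracer(tracer)


@dataclass(frozen=True)
class RoutingFractions:
    """Mixture weights of the carbon routes feeding citrate.

    The five base routes (oxidative glucose, oxidative glutamine, reductive
    glutamine, pyruvate carboxylase, fully unlabelled) form a simplex.
    ``f_fix`` is orthogonal: the fraction of citrate molecules whose
    carboxylation-derived carbon (position 5) carries a bicarbonate label.
    """

    f_ox_glc: float = 0.0
    f_ox_gln: float = 0.0
    f_red_gln: float = 0.0
    f_pc: float = 0.0
    f_unlab: float = 0.0
    f_fix: float = 0.0

    _BASE = ("f_ox_glc", "f_ox_gln", "f_red_gln", "f_pc", "f_unlab")

    def __post_init__(self) -> None:
        for name in self._BASE + ("f_fix",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(getattr(self, name) for name in self._BASE)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base route fractions sum to {total}, expected 1 within 1e-9")

    def base_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self._BASE])


class FragmentCatalogError(KeyError):
    """A fragment not present in the fragment catalogue was requested."""


_LOST_POSITION = {"none": None, "carboxyl_C6": CARBOXYLATION_POSITION, "oaa_carboxyl": CARBOXYLATION_POSITION}


@dataclass(frozen=True)
class FragmentDefinition:
    """One GC-MS fragment of a derivatized metabolite.

    ``extra_carbons`` counts derivatization-reagent carbons retained in the
    fragment; they widen the natural-abundance envelope but never carry
    tracer label.
    """

    metabolite: str
    nominal_mz: int
    metabolite_carbons_retained: int
    lost_carbon_position: str = "none"
    derivatization: str = "MSTFA"
    extra_carbons: int = 0

    def __post_init__(self) -> None:
        if self.nominal_mz <= 0:
            raise ValueError("nominal_mz must be positive")
        if self.lost_carbon_position not in _LOST_POSITION:
            raise ValueError(f"unknown lost_carbon_position {self.lost_carbon_position!r}")
        if self.metabolite_carbons_retained < 0:
            raise ValueError("metabolite_carbons_retained must be non-negative")
        if self.extra_carbons < 0:
            raise ValueError("extra_carbons must be non-negative")

    @property
    def lost_position(self) -> int | None:
        return _LOST_POSITION[self.lost_carbon_position]

    @property
    def total_carbons(self) -> int:
        return self.metabolite_carbons_retained + self.extra_carbons


#: Citrate fragment catalogue.  273 m/z is the MSTFA-derived C5 fragment
#: (loses the carboxylation-derived carbon); 375 m/z the full molecule under
#: MSTFA; 459 m/z the full molecule under MBTSTFA.  extra_carbons are
#: reagent-carbon assumptions (TMS = 3 C, TBDMS = 6 C per group).
CITRATE_FRAGMENTS: dict[int, FragmentDefinition] = {
    273: FragmentDefinition("citrate", 273, 5, "oaa_carboxyl", "MSTFA", 6),
    375: FragmentDefinition("citrate", 375, 6, "none", "MSTFA", 9),
    459: FragmentDefinition("citrate", 459, 6, "none", "MBTSTFA", 12),
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal CV plus an additive Gaussian floor."""

    multiplicative_cv: float = 0.0
    additive_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValueError("multiplicative_cv must be >= 0")
        if self.additive_floor < 0:
            raise ValueError("additive_floor must be >= 0")

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.multiplicative_cv > 0:
            sigma = np.sqrt(np.log1p(self.multiplicative_cv**2))
            out = out * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=out.shape)
        if self.additive_floor > 0:
            out = out + rng.normal(0.0, self.additive_floor, size=out.shape)
        return np.clip(out, 0.0, None)


def _route_pattern(route: str, tracer: Tracer) -> frozenset[int]:
    """Labelled citrate positions contributed by a base route under a tracer."""
    if tracer == Tracer.U13C6_GLUCOSE:
        if route == "f_ox_glc":
            return frozenset(ACETYL_POSITIONS)
        if route == "f_pc":
            # OAA from fully labelled pyruvate + cold CO2: the carboxylation
            # carboxyl (position 5) stays unlabelled.
            return frozenset(p for p in OAA_POSITIONS if p != CARBOXYLATION_POSITION)
    elif tracer == Tracer.U13C5_GLUTAMINE:
        if route == "f_ox_gln":
            return frozenset(OAA_POSITIONS)
        if route == "f_red_gln":
            # alpha-KG m+5 retains all five glutamine carbons; the added CO2
            # carbon (position 5) is cold.
            return frozenset(range(N_CITRATE_CARBONS)) - {CARBOXYLATION_POSITION}
    return frozenset()


def species_distribution(fractions: RoutingFractions, tracer) -> dict[frozenset[int], float]:
    """Distribution over per-carbon label patterns implied by the routing mix.

    Under the bicarbonate tracer, fixation independently labels position 5
    of a fraction ``f_fix`` of molecules, on top of whichever base route the
    molecule took (all of which are cold under that tracer).
    """
    tracer = _as_tracer(tracer)
    dist: dict[frozenset[int], float] = {}
    for route in RoutingFractions._BASE:
        w = getattr(fractions, route)
        if w == 0.0:
            continue
        pattern = _route_pattern(route, tracer)
        if tracer == Tracer.C13_BICARBONATE and fractions.f_fix > 0:
            hot = pattern | {CARBOXYLATION_POSITION}
            dist[hot] = dist.get(hot, 0.0) + w * fractions.f_fix
            w = w * (1.0 - fractions.f_fix)
        dist[pattern] = dist.get(pattern, 0.0) + w
    return dist


def fragment_mid(distribution: Mapping[frozenset[int], float], fragment: FragmentDefinition) -> MIDVector:
    """Marginalize a label-pattern distribution onto one fragment's shifts."""
    masses = np.zeros(fragment.metabolite_carbons_retained + 1)
    lost = fragment.lost_position
    for pattern, weight in distribution.items():
        shift = sum(1 for p in pattern if p != lost)
        masses[shift] += weight
    return MIDVector(masses)


def simulate_citrate_mids(
    fractions: RoutingFractions,
    tracer,
    fragments: Iterable[FragmentDefinition | int] = (273, 375, 459),
) -> dict[int, MIDVector]:
    """Tracer-derived citrate MIDs per fragment, before natural abundance.

    Exactly linear in the routing fractions: the MID of a mixture is the
    fraction-weighted sum of single-route MIDs.
    """
    dist = species_distribution(fractions, tracer)
    out: dict[int, MIDVector] = {}
    for frag in fragments:
        if isinstance(frag, int):
            if frag not in CITRATE_FRAGMENTS:
                raise FragmentCatalogError(f"fragment {frag} m/z not in the citrate catalogue")
            frag = CITRATE_FRAGMENTS[frag]
        elif frag.metabolite == "citrate" and frag.nominal_mz not in CITRATE_FRAGMENTS:
            raise FragmentCatalogError(f"fragment {frag.nominal_mz} m/z not in the citrate catalogue")
        out[frag.nominal_mz] = fragment_mid(dist, frag)
    return out


def generate_intensity_table(
    mids: Mapping[int, MIDVector],
    quantities: Mapping[str, float],
    p13c: float = NATURAL_13C,
    fragments: Mapping[int, FragmentDefinition] | None = None,
    noise: NoiseModel | None = None,
    internal_standard_area: float = 1e6,
    sample_names: Sequence[str] = ("S1",),
) -> pd.DataFrame:
    """Emit a GC-MS-style isotopologue intensity table.

    Each fragment's tracer-derived MID is convolved with the binomial
    natural-abundance envelope over all its carbons (metabolite + reagent),
    scaled by the metabolite quantity, perturbed by the noise model, and
    written as one row per mass shift with one intensity column per sample.
    A cinnamic-acid internal-standard row is appended per the schema.
    """
    if not 0.0 <= p13c <= 0.05:
        raise ValueError(f"p13c={p13c} outside [0, 0.05]")
    fragments = dict(fragments) if fragments is not None else dict(CITRATE_FRAGMENTS)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)

    records: list[list] = []
    blocks: list[np.ndarray] = []
    for mz, mid in mids.items():
        if mz not in fragments:
            raise FragmentCatalogError(f"fragment {mz} m/z missing from the fragment catalogue")
        frag = fragments[mz]
        quantity = quantities.get(frag.metabolite)
        if quantity is None:
            raise ValueError(f"no quantity given for metabolite {frag.metabolite!r}")
        if quantity < 0:
            raise ValueError(f"negative quantity for metabolite {frag.metabolite!r}")
        envelope = natural_abundance_envelope(frag.total_carbons, p13c)
        observed = convolve_envelope(mid, envelope).masses * quantity
        for shift, base in enumerate(observed):
            records.append([frag.metabolite, mz, shift])
            blocks.append(noise.perturb(np.full(len(sample_names), base), rng))
    records.append([INTERNAL_STANDARD, INTERNAL_STANDARD_MZ, 0])
    blocks.append(noise.perturb(np.full(len(sample_names), float(internal_standard_area)), rng))

    table = pd.DataFrame(records, columns=["metabolite", "fragment_mz", "mass_shift"])
    table[list(sample_names)] = np.vstack(blocks)
    return table


def generate_expression_experiments(
    n_genes: int,
    n_regulated: int,
    log2_effect: float = 2.0,
    replicate_cv: float = 0.2,
    n_experiments: int = 3,
    seed: int = 0,
):
    """Replicate sample/control log2 expression experiments with planted truth.

    Regulated genes carry the signed ``log2_effect`` consistently across all
    experiments; noise is intensity-dependent (larger at low expression, a
    hallmark of array data).  Returns an
    :class:`~sirmkit.expression.ExperimentSet` and a truth table with
    columns ``regulated`` (bool) and ``sign`` (+1/-1/0).
    """
    from .expression import Experiment, ExperimentSet

    if n_regulated > n_genes:
        raise ValueError("n_regulated cannot exceed n_genes")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    base = rng.uniform(6.0, 14.0, n_genes)

    effect = np.zeros(n_genes)
    sign = np.zeros(n_genes, dtype=int)
    if n_regulated:
        reg_idx = rng.choice(n_genes, size=n_regulated, replace=False)
        reg_sign = rng.choice([-1, 1], size=n_regulated)
        effect[reg_idx] = reg_sign * log2_effect
        sign[reg_idx] = reg_sign

    # Spread grows ~4x towards the low-intensity end of the 6..14 log2 range.
    noise_sd = replicate_cv * (1.0 + 3.0 * np.exp(-(base - 6.0) / 2.0))

    experiments = []
    for e in range(n_experiments):
        control = base + rng.normal(0.0, noise_sd)
        sample = base + effect + rng.normal(0.0, noise_sd)
        data = pd.DataFrame({"control": control, "sample": sample}, index=genes)
        experiments.append(
            Experiment(name=f"exp{e + 1}", data=data, roles={"control": "control", "sample": "sample"})
        )
    truth = pd.DataFrame({"regulated": sign != 0, "sign": sign}, index=genes)
    return ExperimentSet(experiments), truth


def generate_binary_association_dataset(
    n_samples: int,
    p_a: float,
    p_b: float,
    mode: str = "independent",
    strength: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two boolean high-expression call vectors with a planted association.

    ``mode='exclusive'`` depletes joint highs (strength 1 forbids them);
    ``mode='cooccurring'`` enriches them.  Marginal high frequencies
    approximate ``p_a`` and ``p_b``.
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("p_a and p_b must lie in (0, 1)")
    if mode not in ("independent", "exclusive", "cooccurring"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = rng.random(n_samples) < p_a

    if mode == "independent":
        b = rng.random(n_samples) < p_b
        return a, b
    if mode == "exclusive":
        p_b_given_a = p_b * (1.0 - strength)
    else:
        p_b_given_a = p_b + strength * (1.0 - p_b)
    # Rebalance the A-negative stratum to hold the B marginal at p_b.
    p_b_given_not_a = np.clip((p_b - p_a * p_b_given_a) / (1.0 - p_a), 0.0, 1.0)
    u = rng.random(n_samples)
    b = np.where(a, u < p_b_given_a, u < p_b_given_not_a)
    return a, b
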