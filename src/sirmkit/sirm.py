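"""The pSIRM quantification chain.

Operates on isotopologue tables: tidy frames with columns ``metabolite``,
``fragment_mz``, ``mass_shift`` and one intensity column per sample, plus a
cinnamic-acid internal-standard row.  Three steps compose:

1. internal-standard normalization (metabolite quantity relative to the
   spiked cinnamic acid, per sample);
2. label-incorporation estimation against an unlabelled reference spectrum
   (a measured identification standard carrying natural 13C abundance, or a
   theoretical binomial envelope as fallback);
3. the labelled quantity: incorporation x normalized quantity, the
   per-metabolite pathway-activity readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mid import MIDVector, NATURAL_13C, natural_abundance_envelope
from .synthetic import INTERNAL_STANDARD, FragmentDefinition, TracerSpec

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["metabolite", "fragment_mz", "mass_shift"]


class InternalStandardError(ValueError):
    """Internal-standard row missing or non-positive for some sample."""


class UndefinedMIDError(ValueError):
    """All intensities of a fragment are zero; its MID is undefined."""


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"isotopologue table lacks columns {missing}")
    if table.duplicated(KEY_COLUMNS).any():
        dupes = table.loc[table.duplicated(KEY_COLUMNS), KEY_COLUMNS]
        raise ValueError(f"duplicate (metabolite, fragment, shift) rows: {dupes.values.tolist()}")
    values = table[sample_columns(table)]
    if (values.to_numpy() < 0).any():
        raise ValueError("negative intensities in isotopologue table")


def average_technical_duplicates(table: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Average technical-duplicate sample columns on the intensity scale.

    ``groups`` maps sample column -> duplicate-group label; the averaged
    column keeps the group label as its name.
    """
    validate_table(table)
    out = table[KEY_COLUMNS].copy()
    by_group: dict[str, list[str]] = {}
    for col in sample_columns(table):
        by_group.setdefault(groups.get(col, col), []).append(col)
    for group, cols in by_group.items():
        out[group] = table[cols].mean(axis=1)
    return out


def internal_standard_intensities(table: pd.DataFrame) -> pd.Series:
    """Per-sample cinnamic-acid intensity (hard error if absent or zero)."""
    rows = table[table["metabolite"] == INTERNAL_STANDARD]
    if rows.empty:
        raise InternalStandardError("no internal-standard (cinnamic acid) row in table")
    intensities = rows[sample_columns(table)].sum(axis=0)
    bad = intensities.index[intensities <= 0]
    if len(bad):
        raise InternalStandardError(f"internal standard non-positive in sample(s) {list(bad)}")
    return intensities


def quantifier_fragments(
    table: pd.DataFrame, fragments: Mapping[int, FragmentDefinition] | None = None
) -> dict[str, int]:
    """Designated quantifier fragment per metabolite.

    Defaults to the fragment with the most retained metabolite carbons when
    a catalogue entry exists, otherwise the highest m/z observed.
    """
    quantifier: dict[str, int] = {}
    for metabolite, sub in table.groupby("metabolite"):
        if metabolite == INTERNAL_STANDARD:
            continue
        mzs = sorted(sub["fragment_mz"].unique())
        if fragments:
            known = [mz for mz in mzs if mz in fragments]
            if known:
                quantifier[metabolite] = max(
                    known, key=lambda mz: (fragments[mz].metabolite_carbons_retained, mz)
                )
                continue
        quantifier[metabolite] = max(mzs)
    return quantifier


def normalize_to_internal_standard(
    table: pd.DataFrame, fragments: Mapping[int, FragmentDefinition] | None = None
) -> pd.DataFrame:
    """Metabolite quantities relative to the internal standard, per sample.

    The quantity of a metabolite is the summed intensity over mass shifts of
    its quantifier fragment, divided by the sample's cinnamic-acid
    intensity; invariant to any per-sample global intensity scale.
    """
    validate_table(table)
    istd = internal_standard_intensities(table)
    cols = sample_columns(table)
    quantifier = quantifier_fragments(table, fragments)
    rows = {}
    for metabolite, mz in quantifier.items():
        sub = table[(table["metabolite"] == metabolite) & (table["fragment_mz"] == mz)]
        rows[metabolite] = sub[cols].sum(axis=0) / istd
    out = pd.DataFrame(rows).T
    out.index.name = "metabolite"
    return out


def raw_mid(table: pd.DataFrame, metabolite: str, fragment_mz: int, sample: str) -> MIDVector:
    """Renormalized MID of one fragment in one sample (absent shifts are 0)."""
    sub = table[(table["metabolite"] == metabolite) & (table["fragment_mz"] == fragment_mz)]
    if sub.empty:
        raise KeyError(f"no rows for {metabolite} fragment {fragment_mz}")
    if sample not in sub.columns:
        raise KeyError(f"sample {sample!r} not in table")
    shifts = sub["mass_shift"].to_numpy()
    intensities = np.zeros(int(shifts.max()) + 1)
    intensities[shifts] = sub[sample].to_numpy()
    if intensities.sum() <= 0:
        raise UndefinedMIDError(f"{metabolite} fragment {fragment_mz} all-zero in sample {sample!r}")
    return MIDVector.from_intensities(intensities)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Unlabelled MID of one fragment, measured on an identification standard."""

    metabolite: str
    fragment_mz: int
    mid: MIDVector

    def __post_init__(self) -> None:
        if self.mid.masses.argmax() != 0:
            raise ValueError("reference spectrum must have its modal mass at shift 0")


def binomial_reference(fragment: FragmentDefinition, p13c: float = NATURAL_13C) -> ReferenceSpectrum:
    """Theoretical natural-abundance reference (fallback when no standard exists)."""
    env = natural_abundance_envelope(fragment.total_carbons, p13c)
    return ReferenceSpectrum(fragment.metabolite, fragment.nominal_mz, MIDVector(env))


@dataclass(frozen=True)
class LabelIncorporation:
    """Label-incorporation estimate plus the excess (labelled) MID.

    ``corrected_mid`` is the natural-abundance-corrected MID: the
    unlabelled component collapsed onto m+0 plus the excess at shifts >= 1,
    renormalized — the tracer-derived MID the routing stage consumes.
    """

    fraction: float
    excess_mid: MIDVector | None
    clipped_mass: float  # negative excess clipped to 0, retained for QC
    corrected_mid: MIDVector | None = None


def label_incorporation(sample_mid: MIDVector, reference: ReferenceSpectrum) -> LabelIncorporation:
    """Excess over the natural-abundance reference, scaled to the m+0 mass.

    The unlabelled component is reconstructed by scaling the reference so
    its m+0 matches the sample's: expected_j = s0 * ref_j / ref_0.  Masses
    above expectation at shifts >= 1 are label-derived excess; the
    incorporation is excess / (s0 + excess), clipped to [0, 1].  Invariant
    to global intensity scaling of the sample.
    """
    ref = reference.mid
    if ref.mass(0) <= 0:
        raise ValueError("degenerate reference: zero mass at shift 0")
    n = max(len(sample_mid), len(ref))
    s = sample_mid.padded(n)
    r = ref.padded(n)
    expected = s[0] * r / r[0]
    diff = s - expected
    excess = np.clip(diff, 0.0, None)
    excess[0] = 0.0
    clipped = float(np.clip(-diff[1:], 0.0, None).sum())
    if clipped > 0:
        logger.info(
            "label_incorporation: clipped %.3g negative excess for %s fragment %s",
            clipped, reference.metabolite, reference.fragment_mz,
        )
    total_excess = float(excess.sum())
    denom = float(s[0]) + total_excess
    if denom <= 0:
        return LabelIncorporation(0.0, None, clipped)
    fraction = float(np.clip(total_excess / denom, 0.0, 1.0))
    excess_mid = MIDVector(excess / total_excess) if total_excess > 0 else None
    corrected = excess.copy()
    corrected[0] = s[0]
    corrected_mid = MIDVector(corrected / denom)
    return LabelIncorporation(fraction, excess_mid, clipped, corrected_mid)


def labelled_quantities(
    table: pd.DataFrame,
    references: Mapping[tuple[str, int], ReferenceSpectrum],
    tracer: TracerSpec | None = None,
    fragments: Mapping[int, FragmentDefinition] | None = None,
) -> pd.DataFrame:
    """Labelled quantity per metabolite/fragment/sample.

    Composes internal-standard normalization with label incorporation:
    ``labelled_quantity = label_incorporation * normalized_quantity``.
    """
    validate_table(table)
    normalized = normalize_to_internal_standard(table, fragments)
    tracer_name = tracer.name.value if tracer is not None else None
    records = []
    for (metabolite, mz), sub in table.groupby(["metabolite", "fragment_mz"]):
        if metabolite == INTERNAL_STANDARD:
            continue
        ref = references.get((metabolite, mz))
        if ref is None:
            raise KeyError(f"no reference spectrum for {metabolite} fragment {mz}")
        for sample in sample_columns(table):
            try:
                mid = raw_mid(table, metabolite, mz, sample)
                inc = label_incorporation(mid, ref)
            except (UndefinedMIDError, ValueError) as err:
                raise type(err)(f"{metabolite}/{mz}/{sample}: {err}") from err
            quantity = float(normalized.loc[metabolite, sample])
            records.append(
                {
                    "metabolite": metabolite,
                    "fragment_mz": mz,
                    "sample": sample,
                    "tracer": tracer_name,
                    "label_incorporation": inc.fraction,
                    "normalized_quantity": quantity,
                    "labelled_quantity": inc.fraction * quantity,
                }
            )
    return pd.DataFrame.from_records(records)


def excess_mids(
    table: pd.DataFrame,
    references: Mapping[tuple[str, int], ReferenceSpectrum],
    sample: str,
) -> dict[tuple[str, int], MIDVector]:
    """Excess (labelled-component) MIDs for every referenced fragment in a sample."""
    out: dict[tuple[str, int], MIDVector] = {}
    for (metabolite, mz), ref in references.items():
        mid = raw_mid(table, metabolite, mz, sample)
        inc = label_incorporation(mid, ref)
        if inc.excess_mid is not None:
            out[(metabolite, mz)] = inc.excess_mid
    return out


def natural_abundance_correct(sample_mid: MIDVector, fragment: FragmentDefinition,
                              p13c: float = NATURAL_13C) -> MIDVector:
    """Deconvolve the binomial natural-abundance envelope from a measured MID.

    Solves the non-negative least-squares system E m = s, where E is the
    convolution matrix of the envelope over all fragment carbons and m is
    supported on the metabolite's mass shifts.  Exact on noise-free data;
    under noise the non-negativity constraint keeps the result a valid MID.
    This is the correction the routing stage consumes; the empirical-
    reference path (:func:`label_incorporation`) remains the primary
    incorporation estimator.
    """
    from scipy.optimize import nnls

    env = natural_abundance_envelope(fragment.total_carbons, p13c)
    n_out = fragment.metabolite_carbons_retained + 1
    n_rows = max(len(sample_mid), n_out + len(env) - 1)
    E = np.zeros((n_rows, n_out))
    for j in range(n_out):
        E[j:j + len(env), j] = env
    s = np.zeros(n_rows)
    s[: len(sample_mid)] = sample_mid.masses
    solution, _ = nnls(E, s)
    if solution.sum() <= 0:
        raise UndefinedMIDError(
            f"abundance correction of {fragment.metabolite} {fragment.nominal_mz} left no mass"
        )
    return MIDVector.from_intensities(solution)


def corrected_mids(
    table: pd.DataFrame,
    references: Mapping[tuple[str, int], ReferenceSpectrum],
    sample: str,
) -> dict[tuple[str, int], MIDVector]:
    """Natural-abundance-corrected MIDs (m+0 + excess) per referenced fragment."""
    out: dict[tuple[str, int], MIDVector] = {}
    for (metabolite, mz), ref in references.items():
        mid = raw_mid(table, metabolite, mz, sample)
        inc = label_incorporation(mid, ref)
        if inc.corrected_mid is not None:
            out[(metabolite, mz)] = inc.corrected_mid
    return out
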