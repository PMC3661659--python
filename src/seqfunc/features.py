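"""Protein feature vectors organized into named feature groups.

Feature-based function prediction describes each protein by a fixed
vector of sequence-derived attributes grouped into named blocks
(amino-acid composition, global sequence features, and the outputs of
external structure/localization/modification predictors).  Model
selection removes or keeps whole groups, never single columns, so the
layout — an ordered list of ``(group, offset, dimension)`` — is part of
the data structure.

Two groups are computed natively from the sequence; the remaining
groups are provider contracts: callables ``(accession, sequence) ->
vector`` registered under a provider id.  Running the actual external
predictors is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy
_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

# Average residue masses (Da); water added once per chain.
_RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
_WATER_MASS = 18.01524

# Henderson-Hasselbalch pKa values (EMBOSS set).
_PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_PKA_NTERM, _PKA_CTERM = 8.6, 3.6

CHARGED_RESIDUES = set("DEKR")

COMPOSITION_GROUP = "amino_acid_composition"
SEQUENCE_GROUP = "sequence_features"
NATIVE_PROVIDER = "native"

#: Names of the global sequence features, in vector order.
SEQUENCE_FEATURE_NAMES = ("length", "molecular_weight", "mean_hydropathy",
                          "net_charge_ph7", "fraction_charged")


class FeatureError(ValueError):
    """Raised for layout mismatches, missing providers, bad dimensions."""


@dataclass(frozen=True)
class FeatureGroupSpec:
    name: str
    dimension: int
    provider_id: str

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise FeatureError(f"group {self.name!r}: dimension must be > 0")


def default_registry(predictor_dimension: int = 4) -> list[FeatureGroupSpec]:
    """The standard 14-group registry.

    Composition (20) and global sequence features (5) are native; the
    twelve predictor-derived groups default to a configurable dimension
    since their exact upstream feature lists are provider contracts.
    """
    predictor_groups = [
        "transmembrane_segments", "secondary_structure",
        "disordered_regions", "signal_peptides",
        "subcellular_localization", "pest_regions",
        "low_complexity_regions", "coiled_coils",
        "phosphorylation_sites", "n_glycosylation_sites",
        "o_glycosylation_sites", "glycation_sites",
    ]
    registry = [
        FeatureGroupSpec(COMPOSITION_GROUP, 20, NATIVE_PROVIDER),
        FeatureGroupSpec(SEQUENCE_GROUP, 5, NATIVE_PROVIDER),
    ]
    registry += [FeatureGroupSpec(name, predictor_dimension, f"mock:{name}")
                 for name in predictor_groups]
    return registry


# -- native feature groups ----------------------------------------------------

def _net_charge(counts: Mapping[str, int], ph: float = 7.0) -> float:
    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def neg(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (pka - ph))

    charge = pos(_PKA_NTERM) - neg(_PKA_CTERM)
    for aa, pka in _PKA_POSITIVE.items():
        charge += counts.get(aa, 0) * pos(pka)
    for aa, pka in _PKA_NEGATIVE.items():
        charge -= counts.get(aa, 0) * neg(pka)
    return charge


def native_features(sequence: str) -> dict[str, np.ndarray]:
    """Compute the two native groups from an amino-acid sequence.

    Composition: fractions of the 20 standard residues; non-standard
    letters (X, B, Z, U, ...) are tolerated but excluded from the
    denominator.  Sequence features: length, molecular weight, mean
    Kyte-Doolittle hydropathy, net charge at pH 7 and the fraction of
    charged (D/E/K/R) residues.
    """
    sequence = sequence.upper()
    if not sequence:
        raise FeatureError("empty sequence")
    counts = {aa: sequence.count(aa) for aa in AA_ALPHABET}
    n_standard = sum(counts.values())
    if n_standard == 0:
        raise FeatureError("sequence contains no standard residues")
    composition = np.array([counts[aa] / n_standard for aa in AA_ALPHABET])
    mass = sum(counts[aa] * _RESIDUE_MASS[aa] for aa in AA_ALPHABET)
    mass += _WATER_MASS
    gravy = sum(counts[aa] * _HYDROPATHY[aa] for aa in AA_ALPHABET) / n_standard
    charged = sum(counts[aa] for aa in CHARGED_RESIDUES) / n_standard
    seq_feats = np.array([float(len(sequence)), mass, gravy,
                          _net_charge(counts), charged])
    return {COMPOSITION_GROUP: composition, SEQUENCE_GROUP: seq_feats}


def native_provider(accession: str, sequence: str,
                    group: str) -> np.ndarray:
    return native_features(sequence)[group]


# -- vectors and matrices -----------------------------------------------------

FeatureProvider = Callable[[str, str], np.ndarray]


@dataclass
class FeatureVector:
    """One protein's features with their group layout."""

    accession: str
    values: np.ndarray
    layout: list[tuple[str, int, int]]  # (group, offset, dimension)

    def group(self, name: str) -> np.ndarray:
        for group, offset, dim in self.layout:
            if group == name:
                return self.values[offset:offset + dim]
        raise FeatureError(f"unknown group {name!r}")

    def group_names(self) -> list[str]:
        return [g for g, _, _ in self.layout]


def assemble(accession: str,
             sequence: str,
             providers: Mapping[str, FeatureProvider],
             registry: Sequence[FeatureGroupSpec]) -> FeatureVector:
    """Concatenate all registry groups for one protein, in registry order.

    Native groups resolve through the built-in sequence calculators; any
    other group looks up its ``provider_id`` in ``providers``.  A
    missing provider or a wrong-dimension return is an error naming the
    group — absent features are never silently defaulted.
    """
    blocks: list[np.ndarray] = []
    layout: list[tuple[str, int, int]] = []
    offset = 0
    for spec in registry:
        if spec.provider_id == NATIVE_PROVIDER:
            block = native_provider(accession, sequence, spec.name)
        else:
            provider = providers.get(spec.provider_id)
            if provider is None:
                raise FeatureError(
                    f"group {spec.name!r}: no provider {spec.provider_id!r}")
            block = np.asarray(provider(accession, sequence), dtype=float)
        if block.shape != (spec.dimension,):
            raise FeatureError(
                f"group {spec.name!r}: provider returned shape "
                f"{block.shape}, expected ({spec.dimension},)")
        blocks.append(block)
        layout.append((spec.name, offset, spec.dimension))
        offset += spec.dimension
    return FeatureVector(accession, np.concatenate(blocks), layout)


class FeatureMatrix:
    """Proteins x features, sharing one group layout."""

    def __init__(self, accessions: Sequence[str], values: np.ndarray,
                 layout: Sequence[tuple[str, int, int]]) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(accessions):
            raise FeatureError("values must be (n_proteins, n_features)")
        total = sum(dim for _, _, dim in layout)
        if values.shape[1] != total:
            raise FeatureError("layout does not cover the value columns")
        self.accessions = list(accessions)
        self.values = values
        self.layout = [tuple(entry) for entry in layout]
        self._row_index = {a: i for i, a in enumerate(self.accessions)}

    @classmethod
    def from_vectors(cls, vectors: Sequence[FeatureVector]) -> "FeatureMatrix":
        if not vectors:
            raise FeatureError("no vectors")
        layout = vectors[0].layout
        for v in vectors[1:]:
            if v.layout != layout:
                raise FeatureError("inconsistent layouts")
        return cls([v.accession for v in vectors],
                   np.vstack([v.values for v in vectors]), layout)

    def group_names(self) -> list[str]:
        return [g for g, _, _ in self.layout]

    def rows(self, accessions: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._row_index[a] for a in accessions]
        except KeyError as exc:
            raise FeatureError(f"unknown accession {exc.args[0]!r}") from exc
        return self.values[idx]

    def vector(self, accession: str) -> FeatureVector:
        return FeatureVector(accession, self.rows([accession])[0],
                             list(self.layout))

    def drop_groups(self, removed: Iterable[str]) -> "FeatureMatrix":
        """Delete whole feature groups; the layout re-packs left-to-right."""
        removed = set(removed)
        unknown = removed - set(self.group_names())
        if unknown:
            raise FeatureError(f"unknown groups {sorted(unknown)}")
        keep_cols: list[int] = []
        new_layout: list[tuple[str, int, int]] = []
        offset = 0
        for group, start, dim in self.layout:
            if group in removed:
                continue
            keep_cols.extend(range(start, start + dim))
            new_layout.append((group, offset, dim))
            offset += dim
        return FeatureMatrix(self.accessions, self.values[:, keep_cols],
                             new_layout)

    def select_groups(self, retained: Iterable[str]) -> "FeatureMatrix":
        retained = set(retained)
        return self.drop_groups(set(self.group_names()) - retained)

    # -- TSV round trip ------------------------------------------------------

    def to_tsv(self, path) -> None:
        columns = [f"{group}:{i}" for group, _, dim in self.layout
                   for i in range(dim)]
        frame = pd.DataFrame(self.values, columns=columns)
        frame.insert(0, "accession", self.accessions)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t")
        accessions = frame["accession"].astype(str).tolist()
        layout: list[tuple[str, int, int]] = []
        for col in frame.columns[1:]:
            group = col.rsplit(":", 1)[0]
            if layout and layout[-1][0] == group:
                name, offset, dim = layout[-1]
                layout[-1] = (name, offset, dim + 1)
            else:
                offset = layout[-1][1] + layout[-1][2] if layout else 0
                layout.append((group, offset, 1))
        return cls(accessions, frame.iloc[:, 1:].to_numpy(float), layout)


# -- min-max scaling ----------------------------------------------------------

@dataclass
class ScalingModel:
    """Per-feature (min, max) learned from training rows only.

    The transform maps training values into [0, 1]; unseen values are
    clipped; degenerate features (min == max) map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        scaled = (values - self.mins) / safe
        scaled = np.where(span > 0, scaled, 0.0)
        return np.clip(scaled, 0.0, 1.0)


def fit_scaling(values: np.ndarray) -> ScalingModel:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise FeatureError("cannot fit scaling on an empty matrix")
    return ScalingModel(mins=values.min(axis=0), maxs=values.max(axis=0))
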