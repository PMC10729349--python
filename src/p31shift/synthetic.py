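"""Seeded generator of single-phosphorus molecules with known ground truth.

Every predictor in this package is testable without any external download:
molecules are assembled from a library of common phosphorus substituents
(alkyl, aryl, alkoxy, halide, amino, thio, oxo, ring diyls …) and their
shifts generated by an additive increment model

    δ = b + Σᵢ aᵢ·nᵢ + γ·Σ_{i<j} aᵢaⱼ/10 + N(0, σ²)

with known intercept ``b`` and per-substituent increments ``aᵢ``, an
optional pairwise interaction of strength ``γ`` (the simplest non-linearity
that makes purely linear models degrade while lookup, tree and graph models
do not), and Gaussian noise.  Substituent sampling is Zipf-weighted so rare
substituents form a long tail, as in real shift collections.

Phosphorus valence varies across generated molecules — trivalent P(III),
phosphine oxides/sulfides, phosphonium cations and pentacoordinate P(V) —
which keeps the increment design matrix full rank and is what real
single-phosphorus databases look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from . import chem
from .database import MoleculeRecord

GENERATOR_VERSION = "v1"


@dataclass(frozen=True)
class SubstituentEntry:
    """One library substituent: assembly fragment and its true increment."""

    name: str
    branch: str  # SMILES fragment as attached to P ("=O" for oxo)
    increment: float  # ppm per occurrence
    arity: int = 1  # 1 = monovalent, 2 = ring diyl

    @property
    def key(self) -> str:
        """Canonical extraction key (dummy-atom fragment SMILES), identical
        to what :func:`p31shift.bos.extract_substituents` produces."""
        if self.branch.startswith("="):
            probe = f"[*]{self.branch}"
        elif self.arity == 2:
            probe = f"[*]{self.branch}[*]"
        else:
            probe = f"[*]{self.branch}"
        mol = Chem.MolFromSmiles(probe)
        if mol is None:
            raise ValueError(f"library fragment {self.branch!r} is not valid")
        return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SubstituentLibrary:
    entries: tuple[SubstituentEntry, ...]
    intercept: float  # ppm

    @property
    def monovalent(self) -> list[SubstituentEntry]:
        return [e for e in self.entries if e.arity == 1 and not e.branch.startswith("=")]

    @property
    def divalent(self) -> list[SubstituentEntry]:
        return [e for e in self.entries if e.arity == 2]

    @property
    def oxo(self) -> list[SubstituentEntry]:
        return [e for e in self.entries if e.branch.startswith("=")]

    def increments_by_key(self) -> dict[str, float]:
        return {e.key: e.increment for e in self.entries}


def default_library() -> SubstituentLibrary:
    """Common P substituents with plausible signed increments.

    Electron-donating alkyl groups carry negative increments (they shield
    the phosphorus), perfluoroalkyl and electronegative partners positive
    ones; magnitudes are a few to a few tens of ppm per group.
    """
    entries = (
        SubstituentEntry("hydride", "[H]", -45.0),
        SubstituentEntry("methyl", "C", -7.5),
        SubstituentEntry("ethyl", "CC", -3.0),
        SubstituentEntry("n-propyl", "CCC", -1.5),
        SubstituentEntry("isopropyl", "C(C)C", 2.0),
        SubstituentEntry("tert-butyl", "C(C)(C)C", 8.0),
        SubstituentEntry("phenyl", "c1ccccc1", 1.5),
        SubstituentEntry("vinyl", "C=C", -5.0),
        SubstituentEntry("cyano", "C#N", -30.0),
        SubstituentEntry("trifluoromethyl", "C(F)(F)F", 6.0),
        SubstituentEntry("pentafluoroethyl", "C(F)(F)C(F)(F)F", 10.1),
        SubstituentEntry("hydroxy", "O", 12.0),
        SubstituentEntry("oxide-anion", "[O-]", 5.0),
        SubstituentEntry("methoxy", "OC", 15.0),
        SubstituentEntry("ethoxy", "OCC", 13.0),
        SubstituentEntry("phenoxy", "Oc1ccccc1", 10.0),
        SubstituentEntry("dimethylamino", "N(C)C", 18.0),
        SubstituentEntry("diethylamino", "N(CC)CC", 16.0),
        SubstituentEntry("methylthio", "SC", 9.0),
        SubstituentEntry("phenylthio", "Sc1ccccc1", 7.0),
        SubstituentEntry("fluoro", "F", 30.0),
        SubstituentEntry("chloro", "Cl", 25.0),
        SubstituentEntry("bromo", "Br", 20.0),
        SubstituentEntry("oxo", "=O", -25.0),
        SubstituentEntry("thioxo", "=S", 15.0),
        SubstituentEntry("butane-1,4-diyl", "CCCC", -12.0, arity=2),
        SubstituentEntry("ethylenedioxy", "OCCO", 20.0, arity=2),
    )
    return SubstituentLibrary(entries=entries, intercept=20.0)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_molecules: int = 1000
    noise_sd: float = 2.0  # ppm
    interaction_strength: float = 0.0  # γ
    oxo_probability: float = 0.3  # P=O/P=S chance for trivalent cores
    ring_probability: float = 0.15  # chance of a divalent ring substituent
    # distribution of sigma-bonded substituent slots at P:
    # 3 = P(III)/oxides, 4 = phosphonium cations, 5 = neutral P(V)
    sigma_counts: dict[int, float] = field(
        default_factory=lambda: {3: 0.65, 4: 0.25, 5: 0.10}
    )
    zipf_exponent: float = 1.0  # sampling weight ∝ 1/rank^s
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.sigma_counts.values()) - 1) > 1e-9:
            raise ValueError("sigma_counts probabilities must sum to 1")
        if any(k not in (3, 4, 5) for k in self.sigma_counts):
            raise ValueError("sigma substituent counts must be 3, 4 or 5")


def _assemble_smiles(
    sigma_branches: list[str],
    divalent: str | None,
    oxo: str | None,
    cation: bool,
) -> str:
    core = "[P+]" if cation else "P"
    parts = ""
    if oxo is not None:
        parts += f"({oxo})"
    parts += "".join(f"({b})" for b in sigma_branches)
    if divalent is not None:
        # %99 ring closure cannot collide with digits used inside branches
        return f"{core}%99{parts}{divalent}%99"
    return core + parts


def _true_shift(
    entries: list[SubstituentEntry],
    library: SubstituentLibrary,
    gamma: float,
) -> float:
    incs = [e.increment for e in entries]
    shift = library.intercept + sum(incs)
    if gamma:
        pair = sum(
            incs[i] * incs[j]
            for i in range(len(incs))
            for j in range(i + 1, len(incs))
        )
        shift += gamma * pair / 10.0
    return shift


def generate(
    config: GeneratorConfig, library: SubstituentLibrary | None = None
) -> list[MoleculeRecord]:
    """Sample ``n_molecules`` single-phosphorus records with known shifts.

    Reproducible from the seed; structure sampling and noise use separate
    streams so the same seed yields identical structures at any noise
    level.
    """
    library = library or default_library()
    rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(config.seed + 1_000_003)
    mono = library.monovalent
    ranks = np.arange(1, len(mono) + 1, dtype=float)
    weights = ranks ** (-config.zipf_exponent)
    weights /= weights.sum()
    sigma_vals = sorted(config.sigma_counts)
    sigma_probs = [config.sigma_counts[k] for k in sigma_vals]

    records = []
    noise = noise_rng.normal(0.0, 1.0, config.n_molecules) * config.noise_sd
    for i in range(config.n_molecules):
        n_sigma = int(rng.choice(sigma_vals, p=sigma_probs))
        cation = n_sigma == 4
        oxo_entry = None
        if n_sigma == 3 and library.oxo and rng.random() < config.oxo_probability:
            oxo_entry = library.oxo[rng.integers(len(library.oxo))]
        div_entry = None
        slots = n_sigma
        if (
            library.divalent
            and slots >= 3
            and rng.random() < config.ring_probability
        ):
            div_entry = library.divalent[rng.integers(len(library.divalent))]
            slots -= 2
        chosen = [mono[k] for k in rng.choice(len(mono), size=slots, p=weights)]
        used = chosen + ([div_entry] if div_entry else []) + (
            [oxo_entry] if oxo_entry else []
        )
        smiles = _assemble_smiles(
            [e.branch for e in chosen],
            div_entry.branch if div_entry else None,
            oxo_entry.branch if oxo_entry else None,
            cation,
        )
        graph = chem.parse_structure(smiles)
        shift = _true_shift(used, library, config.interaction_strength) + noise[i]
        records.append(
            MoleculeRecord.from_graph(
                id=f"synth-{i:05d}",
                graph=graph,
                shift_ppm=shift,
                solvent="synthetic",
                reference=f"generator {GENERATOR_VERSION} seed {config.seed}",
                source="synthetic",
            )
        )
    return records


def duplicate_environment_set(
    config: GeneratorConfig,
    library: SubstituentLibrary | None = None,
    duplicate_fraction: float = 0.5,
    n_test: int | None = None,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Training records plus a test set in which a chosen fraction are
    structural duplicates of training records (new ids, same structure and
    shift), guaranteeing deepest-sphere HOSE matches for that fraction."""
    if not 0 <= duplicate_fraction <= 1:
        raise ValueError("duplicate_fraction must be in [0, 1]")
    library = library or default_library()
    train = generate(config, library)
    n_test = n_test if n_test is not None else max(1, config.n_molecules // 4)
    n_dup = int(round(duplicate_fraction * n_test))
    rng = np.random.default_rng(config.seed + 7)
    test: list[MoleculeRecord] = []
    if n_dup:
        picks = rng.choice(len(train), size=n_dup, replace=n_dup > len(train))
        for k, src_idx in enumerate(picks):
            src = train[int(src_idx)]
            test.append(
                MoleculeRecord.from_graph(
                    id=f"dup-{k:05d}",
                    graph=src.graph,
                    shift_ppm=src.shift_ppm,
                    solvent=src.solvent,
                    reference=src.reference,
                    source="synthetic",
                )
            )
    n_fresh = n_test - n_dup
    if n_fresh > 0:
        fresh_cfg = GeneratorConfig(
            n_molecules=n_fresh,
            noise_sd=config.noise_sd,
            interaction_strength=config.interaction_strength,
            oxo_probability=config.oxo_probability,
            ring_probability=config.ring_probability,
            sigma_counts=dict(config.sigma_counts),
            zipf_exponent=config.zipf_exponent,
            seed=config.seed + 10_007,
        )
        for k, r in enumerate(generate(fresh_cfg, library)):
            r.id = f"fresh-{k:05d}"
            test.append(r)
    return train, test
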