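"""Synthetic phenotypic screen with a planted structure-activity-dose rule.

The real screen behind this method is unpublished, so every pipeline stage
is exercised on generated data with the same statistical shape: on the
order of a thousand distinct compounds, the five-dose ladder {1.39, 2.78,
5.56, 11.11, 22.22} uM, a heavily imbalanced outcome marginal (81% *no
change*, 9% *increase*, 10% *decrease*), and effects that depend jointly on
a structural motif and the dose.

Generated molecules have the skeleton::

    sub1 -- ring1(pattern) -- linker -- ring2(pattern) -- sub2

where each benzene ring carries its two attachment points in an *ortho*,
*meta* or *para* arrangement.  All pattern arrangements have identical
atom-feature multisets (same atoms, degrees, H counts), so the planted
rules below are invisible to any topology-blind model -- by construction,
only the wiring differs:

* ortho + ortho rings  -> decrease at doses >= 5.56 uM
* ortho + para rings   -> decrease at doses <  5.56 uM
* para  + para rings   -> increase at doses >= 5.56 uM
* ortho + meta rings   -> increase at doses <  5.56 uM

The pattern-pair frequencies are chosen so the planted label marginal is
exactly the target class distribution and, because the two clauses of each
effect gate on complementary dose ranges, the per-dose label marginal is
flat: dose alone predicts nothing, structure alone predicts nothing a bag
of atoms can see -- the effect is a genuine motif x dose interaction.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .screenlab import CLASSES, ScreenRecord, assign_class

__all__ = [
    "GENERATOR_VERSION",
    "PlantedRule",
    "default_rules",
    "generate_library",
    "plant_screen",
    "pattern_counts",
    "pair_motif",
]

GENERATOR_VERSION = "synthdata-1"

DEFAULT_DOSES = (1.39, 2.78, 5.56, 11.11, 22.22)
DEFAULT_BASELINE = {"increase": 0.09, "no_change": 0.81, "decrease": 0.10}

# ring templates: attachment A and B in ortho/meta/para arrangement
_RING1 = {"ortho": "c1({A})c({B})cccc1", "meta": "c1({A})cc({B})ccc1", "para": "c1({A})ccc({B})cc1"}
_RING2 = {"ortho": "c2c({S})cccc2", "meta": "c2cc({S})ccc2", "para": "c2ccc({S})cc2"}

_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "CCO", "CO", "OC", "OCC", "N", "NC",
    "CN(C)C", "F", "Cl", "Br", "I", "C(F)(F)F", "CC#N", "C(=O)O", "C(=O)N",
    "S(C)(=O)=O", "C=C", "CCN", "SC", "C(=O)C", "CCCl",
)
_LINKERS = (
    "C", "CC", "CCC", "CCCC", "CC(C)", "COC", "COCC", "CNC", "CNCC",
    "C(=O)NC", "CC(=O)NC", "CSC", "C(=O)OC", "C=CC", "CC(O)C", "CCOC",
)

# unordered pattern-pair class -> sampling probability; the planted rules on
# these classes yield the 0.81/0.09/0.10 marginal exactly (see module doc)
_PAIR_CLASS_PROBS = {
    ("ortho", "ortho"): 0.10,
    ("ortho", "para"): 0.10,
    ("para", "para"): 0.09,
    ("meta", "ortho"): 0.09,
    ("meta", "meta"): 0.31,
    ("meta", "para"): 0.31,
}

_PATTERN_SMARTS = {
    "ortho": "[A;!#1]-c:c-[A;!#1]",
    "meta": "[A;!#1]-c:c:c-[A;!#1]",
    "para": "[A;!#1]-c:c:c:c-[A;!#1]",
}
# a para arrangement matches its SMARTS along two symmetric paths
_PATTERN_MULTIPLICITY = {"ortho": 1, "meta": 1, "para": 2}


def pattern_counts(mol: Chem.Mol) -> dict[str, int]:
    """Number of ortho / meta / para disubstituted benzene rings."""
    out = {}
    for name, smarts in _PATTERN_SMARTS.items():
        patt = Chem.MolFromSmarts(smarts)
        out[name] = len(mol.GetSubstructMatches(patt)) // _PATTERN_MULTIPLICITY[name]
    return out


def pair_motif(pattern_a: str, pattern_b: str) -> Callable[[Chem.Mol], bool]:
    """Predicate: the molecule's two rings carry exactly these arrangements."""
    for p in (pattern_a, pattern_b):
        if p not in _PATTERN_SMARTS:
            raise ValueError(f"unknown substitution pattern {p!r}")
    expected = Counter([pattern_a, pattern_b])

    def predicate(mol: Chem.Mol) -> bool:
        counts = pattern_counts(mol)
        return all(counts[p] == expected.get(p, 0) for p in _PATTERN_SMARTS)

    predicate.name = f"rings:{pattern_a}+{pattern_b}"  # type: ignore[attr-defined]
    return predicate


@dataclass(frozen=True)
class PlantedRule:
    """One structure-activity-dose clause.

    ``motif`` is a SMARTS string or a predicate on an RDKit molecule.  The
    ``effect`` label applies when the motif is present and the dose is on
    the active side of ``dose_threshold`` (``active_above=True`` means
    doses >= threshold).  ``baseline`` is the target marginal class
    distribution of the whole screen; ``noise_rate`` flips each final label
    to a random other class with the given probability.
    """

    motif: str | Callable[[Chem.Mol], bool]
    dose_threshold: float
    effect: str
    active_above: bool = True
    baseline: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    noise_rate: float = 0.02

    def __post_init__(self):
        if self.effect not in CLASSES:
            raise ValueError(f"effect must be one of {CLASSES}")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if abs(sum(self.baseline.values()) - 1.0) > 1e-9:
            raise ValueError("baseline class distribution must sum to 1")

    def matches(self, mol: Chem.Mol) -> bool:
        if callable(self.motif):
            return bool(self.motif(mol))
        patt = Chem.MolFromSmarts(self.motif)
        if patt is None:
            raise ValueError(f"invalid motif SMARTS pattern: {self.motif!r}")
        return mol.HasSubstructMatch(patt)

    def active_at(self, dose: float) -> bool:
        return dose >= self.dose_threshold if self.active_above else dose < self.dose_threshold


def default_rules(noise_rate: float = 0.02) -> tuple[PlantedRule, ...]:
    """The four motif x dose clauses matching the generator's pair classes."""
    mid = 5.56
    return (
        PlantedRule(pair_motif("ortho", "ortho"), mid, "decrease", True, noise_rate=noise_rate),
        PlantedRule(pair_motif("ortho", "para"), mid, "decrease", False, noise_rate=noise_rate),
        PlantedRule(pair_motif("para", "para"), mid, "increase", True, noise_rate=noise_rate),
        PlantedRule(pair_motif("meta", "ortho"), mid, "increase", False, noise_rate=noise_rate),
    )


def _build_smiles(p1: str, p2: str, sub1: str, linker: str, sub2: str) -> str:
    return _RING1[p1].format(A=sub1, B=linker + _RING2[p2].format(S=sub2))


def generate_library(n: int, seed: int = 0) -> list[tuple[str, str]]:
    """Generate ``n`` distinct, parsable, structurally diverse SMILES.

    Seeded and reproducible; compound ids are ``SYN-0001`` upward.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([abs(int(seed)), 0x11B])
    classes = list(_PAIR_CLASS_PROBS)
    probs = np.array([_PAIR_CLASS_PROBS[c] for c in classes])
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not generate enough distinct molecules")
        pair = classes[rng.choice(len(classes), p=probs)]
        p1, p2 = (pair if rng.random() < 0.5 else pair[::-1])
        smi = _build_smiles(
            p1, p2,
            _SUBSTITUENTS[rng.choice(len(_SUBSTITUENTS))],
            _LINKERS[rng.choice(len(_LINKERS))],
            _SUBSTITUENTS[rng.choice(len(_SUBSTITUENTS))],
        )
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - templates always parse
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append((f"SYN-{len(out) + 1:04d}", smi))
    return out


def _beta_for(label: str, rng: np.random.Generator) -> float:
    # bands chosen to exercise the inclusive/exclusive labeling boundaries
    if label == "increase":
        return float(rng.uniform(1.3, 1.8))
    if label == "decrease":
        return float(0.7 - rng.uniform(0.0, 0.5))  # (0.2, 0.7]
    return float(rng.uniform(0.7, 1.3))


def plant_screen(
    library: list[tuple[str, str]],
    rule: PlantedRule | Sequence[PlantedRule] | None = None,
    doses: Sequence[float] = DEFAULT_DOSES,
    seed: int = 0,
) -> list[ScreenRecord]:
    """Assign a beta and label to every (compound, dose) pair.

    Records matching a planted clause at an active dose get that clause's
    effect; all other records draw from a background distribution adjusted
    so that the overall class marginal lands on the configured baseline.
    Betas are sampled inside the band that re-thresholds to the label, then
    labels (and betas) are flipped with probability ``noise_rate``.  With
    ``noise_rate = 0``, ``assign_class(beta)`` recovers every planted label.
    """
    if not library:
        raise ValueError("empty library")
    if not doses:
        raise ValueError("need at least one dose")
    rules: tuple[PlantedRule, ...]
    if rule is None:
        rules = default_rules()
    elif isinstance(rule, PlantedRule):
        rules = (rule,)
    else:
        rules = tuple(rule)
    baseline = rules[0].baseline
    noise_rate = rules[0].noise_rate
    rng = np.random.default_rng([abs(int(seed)), 0x5C12EE])

    mols = []
    for cid, smi in library:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable library SMILES for {cid}: {smi!r}")
        mols.append(mol)
    matched_rule: list[PlantedRule | None] = []
    for mol in mols:
        hit = next((r for r in rules if r.matches(mol)), None)
        matched_rule.append(hit)

    # planted labels first, so the background draw can be adjusted to hit
    # the requested overall marginal
    doses = [float(d) for d in doses]
    planted: dict[tuple[int, int], str] = {}
    for i, r in enumerate(matched_rule):
        if r is None:
            continue
        for j, d in enumerate(doses):
            if r.active_at(d):
                planted[(i, j)] = r.effect
    total = len(library) * len(doses)
    planted_frac = {c: 0.0 for c in CLASSES}
    for lab in planted.values():
        planted_frac[lab] += 1.0 / total
    free = 1.0 - sum(planted_frac.values())
    bg = {}
    for c in CLASSES:
        bg[c] = max(baseline.get(c, 0.0) - planted_frac[c], 0.0) / free if free > 0 else 0.0
    norm = sum(bg.values())
    if norm <= 0:
        raise ValueError("planted effects exceed the requested baseline marginal")
    if abs(norm - 1.0) > 0.05:
        warnings.warn(
            "planted fractions are far from the baseline marginal; background "
            "distribution renormalized", stacklevel=2,
        )
    bg = {c: v / norm for c, v in bg.items()}
    bg_classes = list(CLASSES)
    bg_probs = np.array([bg[c] for c in bg_classes])

    records = []
    for i, (cid, smi) in enumerate(library):
        for j, d in enumerate(doses):
            label = planted.get((i, j))
            if label is None:
                label = bg_classes[rng.choice(len(bg_classes), p=bg_probs)]
            if noise_rate > 0 and rng.random() < noise_rate:
                label = rng.permutation([c for c in CLASSES if c != label])[0]
            beta = _beta_for(label, rng)
            assert assign_class(beta) == label
            records.append(
                ScreenRecord(compound_id=cid, smiles=smi, dose=d, beta=beta, label=label)
            )
    return records
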