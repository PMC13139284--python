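"""Synthetic multitask structure-activity data with planted determinants.

Generates chemically valid molecules from a fragment-assembly grammar,
plants substructure-driven potency rules on a sparse compound x task
matrix, and corrupts the raw export (salts, duplicates, mixed units) so
that the curation pipeline has real work to do.  Because every
determinant is known, downstream stages (curation, splitting, modeling,
applicability domain, explainability) can be tested end-to-end without
external bioassay data.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

# -- fragment vocabulary -----------------------------------------------------
# Cores are SMILES templates with one or two substitution sites; decorations
# are substituent fragments valid at those sites.  The decoration classes
# (tertiary amines, carboxylic acids, carbamates, phosphate esters, a
# disulfide) mirror the pharmacophoric fragments that dominate bioactivity
# against the cholinergic / endocannabinoid targets this package models.

CORES: tuple[str, ...] = (
    "c1ccc({0})cc1",             # benzene
    "c1ccc2cc({0})ccc2c1",       # naphthalene
    "C1CCC({0})CC1",             # cyclohexane
    "c1cc({0})ccn1",             # pyridine
    "c1csc({0})c1",              # thiophene
    "c1coc({0})c1",              # furan
    "c1ccc(-c2ccc({0})cc2)cc1",  # biphenyl
    "c1cc({0})cc({1})c1",        # 1,3-disubstituted benzene
    "c1ccc({0})c({1})c1",        # 1,2-disubstituted benzene
    "C1CCN({0})CC1",             # N-substituted piperidine
)

DECORATIONS: tuple[str, ...] = (
    "N(C)C", "CN(C)C", "CCN(CC)CC",       # amines (aryl and tertiary alkyl)
    "C(=O)O", "CC(=O)O",                  # carboxylic acids
    "NC(=O)OC", "OC(=O)NC",               # carbamates
    "OP(=O)(OCC)OCC", "OP(=O)(OC)OC",     # phosphate triesters
    "CSSC",                               # disulfide
    "Cl", "F", "Br",
    "C", "CC", "C(C)C", "C(F)(F)F",
    "O", "OC", "N",
    "C#N", "[N+](=O)[O-]",
    "C(=O)NC", "S(=O)(=O)N", "C(=O)OC",
)

LINKERS: tuple[str, ...] = ("C", "CC", "CCC")
LINKER_PROB = 0.35

COUNTER_IONS: tuple[str, ...] = ("Cl", "Br")

# SMARTS for the plantable activity determinants.
PATTERNS = {
    # acyclic only: ring amines hash to different circular environments,
    # so a ring-inclusive rule would not be representable in bit space
    "tertiary_amine": "[NX3;!R]([CX4])([CX4])[CX4]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "carbamate": "[NX3][CX3](=O)[OX2]",
    "phosphate_ester": "[OX2]P(=O)([OX2])[OX2]",
    "disulfide": "[SX2][SX2]",
}


class Rule(NamedTuple):
    """One planted determinant: molecules matching `pattern` gain `weight`
    potency units (p-scale) on task `task`."""

    task: int
    pattern: str
    weight: float


def default_rules(n_tasks: int) -> list[Rule]:
    """Planted rule set used throughout the test fixtures.

    Two rules (tertiary amine, carboxylic acid) are shared by every task;
    each task additionally carries one task-specific rule, so the shared
    fraction is at least one half -- the regime in which multitask
    learning is expected to help.
    """
    specific = [
        ("carbamate", 1.5),
        ("phosphate_ester", 2.5),
        ("disulfide", 1.0),
        ("tertiary_amine", 1.0),  # re-weighted shared motif
    ]
    rules: list[Rule] = []
    for t in range(n_tasks):
        rules.append(Rule(t, PATTERNS["tertiary_amine"], 2.0))
        rules.append(Rule(t, PATTERNS["carboxylic_acid"], -1.5))
        name, w = specific[t % len(specific)]
        rules.append(Rule(t, PATTERNS[name], w))
    return rules


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study.

    sparsity is the fraction of compound x task cells left unobserved
    (default 0.89, the regime typical of pooled bioassay screens);
    base_potency and noise_sd are on the pIC50/pKi scale; duplicate_rate,
    salt_rate and unit_mix control the raw-export corruption.
    """

    n_compounds: int
    n_tasks: int
    sparsity: float = 0.89
    planted_rules: Sequence[Rule] = ()
    base_potency: float = 5.0
    noise_sd: float = 0.3
    duplicate_rate: float = 0.05
    salt_rate: float = 0.05
    unit_mix: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1 or self.n_tasks < 1:
            raise ValueError("n_compounds and n_tasks must be positive")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        for r in self.planted_rules:
            if not 0 <= r.task < self.n_tasks:
                raise ValueError(f"rule task index {r.task} out of range")


@dataclasses.dataclass
class CorruptionRecord:
    """Ground-truth corruption counts, for reconciling curation reports."""

    n_salted: int = 0
    n_concordant_pairs: int = 0
    n_discordant_pairs: int = 0


@dataclasses.dataclass
class SyntheticDataset:
    molecules: list[str]
    truth: np.ndarray            # n_compounds x n_tasks, noise-free p-values
    mask: np.ndarray             # observation indicator, same shape
    observed: pd.DataFrame       # raw corrupted export
    task_ids: list[str]
    endpoint_types: list[str]    # per task, "IC50" or "Ki"
    rules: list[Rule]
    corruption: CorruptionRecord
    spec: SimulationSpec


def generate_molecules(n: int, seed: int) -> list[str]:
    """Assemble `n` unique, valid molecules from the fragment grammar.

    Molecules are unique by canonical SMILES; output is deterministic for
    a given seed.  Raises RuntimeError when the vocabulary is exhausted
    before `n` unique structures are found.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"fragment vocabulary exhausted: only {len(out)} of {n} "
                f"unique molecules generated"
            )
        core = CORES[rng.integers(len(CORES))]
        n_sites = core.count("{")
        subs = []
        for _ in range(n_sites):
            deco = DECORATIONS[rng.integers(len(DECORATIONS))]
            if rng.random() < LINKER_PROB:
                deco = LINKERS[rng.integers(len(LINKERS))] + deco
            subs.append(deco)
        smiles = core.format(*subs)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    return out


def match_matrix(molecules: Sequence[str], patterns: Sequence[str]) -> np.ndarray:
    """Binary matrix M[i, r] = 1 iff molecule i contains SMARTS pattern r."""
    queries = []
    for p in patterns:
        q = Chem.MolFromSmarts(p)
        if q is None:
            raise ValueError(f"invalid SMARTS pattern: {p}")
        queries.append(q)
    M = np.zeros((len(molecules), len(patterns)), dtype=np.int8)
    for i, smi in enumerate(molecules):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable molecule in input: {smi}")
        for r, q in enumerate(queries):
            M[i, r] = int(mol.HasSubstructMatch(q))
    return M


def plant_activity(molecules: Sequence[str], spec: SimulationSpec) -> SyntheticDataset:
    """Plant rule-driven potencies and emit a corrupted raw export.

    The noise-free truth is ``base_potency + sum of matching rule
    weights`` per cell.  Observed entries carry Gaussian noise of
    ``noise_sd``, are back-converted to IC50/Ki concentrations in mixed
    uM/nM units, and a recorded fraction are salted or duplicated
    (half of the duplicate pairs concordant within 0.3 log units, half
    discordant).
    """
    if len(molecules) == 0:
        raise ValueError("molecules must be non-empty")
    rules = list(spec.planted_rules)
    M = match_matrix(molecules, [r.pattern for r in rules]) if rules else None
    if M is not None:
        for r, rule in enumerate(rules):
            if M[:, r].sum() == 0:
                raise ValueError(
                    f"planted pattern matches zero molecules: {rule.pattern}"
                )

    n, T = len(molecules), spec.n_tasks
    truth = np.full((n, T), spec.base_potency, dtype=float)
    if M is not None:
        for r, rule in enumerate(rules):
            truth[:, rule.task] += rule.weight * M[:, r]

    rng = np.random.default_rng(spec.seed + 1)
    mask = (rng.random((n, T)) >= spec.sparsity).astype(np.int8)
    task_ids = [f"T{t}" for t in range(T)]
    endpoint_types = ["IC50" if t % 2 == 0 else "Ki" for t in range(T)]
    compound_ids = [f"CPD{i:05d}" for i in range(n)]

    corruption = CorruptionRecord()
    rows: list[dict] = []

    def emit(i: int, t: int, p: float):
        smi = molecules[i]
        if rng.random() < spec.salt_rate:
            smi = smi + "." + COUNTER_IONS[rng.integers(len(COUNTER_IONS))]
            corruption.n_salted += 1
        if rng.random() < spec.unit_mix:
            value, units = 10.0 ** (9.0 - p), "nM"
        else:
            value, units = 10.0 ** (6.0 - p), "uM"
        rows.append(
            dict(compound_id=compound_ids[i], smiles=smi, task_id=task_ids[t],
                 endpoint_type=endpoint_types[t], value=value, units=units)
        )

    for i in range(n):
        for t in range(T):
            if not mask[i, t]:
                continue
            p_obs = truth[i, t] + rng.normal(0.0, spec.noise_sd)
            emit(i, t, p_obs)
            if rng.random() < spec.duplicate_rate:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                if rng.random() < 0.5:
                    delta = rng.uniform(0.0, 0.3)
                    corruption.n_concordant_pairs += 1
                else:
                    delta = rng.uniform(0.3, 0.6)
                    corruption.n_discordant_pairs += 1
                emit(i, t, p_obs + sign * delta)

    observed = pd.DataFrame(
        rows, columns=["compound_id", "smiles", "task_id", "endpoint_type",
                       "value", "units"]
    )
    return SyntheticDataset(
        molecules=list(molecules), truth=truth, mask=mask, observed=observed,
        task_ids=task_ids, endpoint_types=endpoint_types, rules=rules,
        corruption=corruption, spec=spec,
    )


def simulate(spec: SimulationSpec) -> SyntheticDataset:
    """Generate molecules and plant activity, enforcing rule prevalence.

    Every planted pattern must occur in 5--95% of the molecules;
    otherwise the molecule pool is regenerated (deterministically) with a
    shifted stream, up to five attempts.
    """
    patterns = sorted({r.pattern for r in spec.planted_rules})
    for attempt in range(5):
        molecules = generate_molecules(spec.n_compounds, spec.seed + 100003 * attempt)
        if not patterns:
            return plant_activity(molecules, spec)
        prev = match_matrix(molecules, patterns).mean(axis=0)
        if np.all((prev >= 0.05) & (prev <= 0.95)):
            return plant_activity(molecules, spec)
    raise RuntimeError(
        "could not generate a molecule pool with all planted patterns at "
        f"5-95% prevalence; last prevalences: {dict(zip(patterns, prev))}"
    )


def marker_bits(
    match_vector: np.ndarray,
    fp_matrix: np.ndarray,
    min_precision: float = 0.95,
    min_support_frac: float = 0.25,
) -> np.ndarray:
    """Fingerprint bits that reliably imply a planted pattern.

    A marker bit is (practically) only set in molecules matching the
    pattern (precision >= ``min_precision``) and is set in a
    non-negligible share of them (support of at least
    ``min_support_frac`` of the pattern prevalence, floored at 2% of
    all molecules).  These are the bits a faithful attribution method
    should rank highly for the pattern's task; low-support bits are
    excluded because their attribution mass is diluted over the rarer
    structural contexts they encode.
    """
    present = fp_matrix.astype(bool)
    match = match_vector.astype(bool)
    support = present.mean(axis=0)
    min_support = max(min_support_frac * match.mean(), 0.02)
    with np.errstate(invalid="ignore"):
        precision = (present & match[:, None]).sum(axis=0) / np.maximum(
            present.sum(axis=0), 1
        )
    return np.where((support >= min_support) & (precision >= min_precision))[0]


def write_dataset(ds: SyntheticDataset, observed_path, truth_path=None) -> None:
    """Write the raw export (and optionally the noise-free truth table)."""
    ds.observed.to_csv(observed_path, index=False)
    if truth_path is not None:
        truth = pd.DataFrame(ds.truth, columns=ds.task_ids)
        truth.insert(0, "smiles", ds.molecules)
        truth.insert(0, "compound_id", [f"CPD{i:05d}" for i in range(len(ds.molecules))])
        truth.to_csv(truth_path, index=False)
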