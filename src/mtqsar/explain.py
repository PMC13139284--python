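"""Model-independent kernel SHAP attribution on fingerprint bits.

Shapley values are estimated by the kernel method: coalitions of bits
are scored by the model with absent bits marginalized over a background
set, and a weighted least-squares fit under the local-accuracy
constraint (base value + sum of contributions = prediction) recovers
per-bit contributions.  Small coalition spaces are enumerated exactly
with the Shapley kernel weights; larger ones are sampled.  Per-task
explanations of the multitask network treat each task head as a scalar
function of the shared fingerprint input.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .featurize import DEFAULT_NBITS, DEFAULT_RADIUS, _mol
from .models import TrainedModel, predict as _model_predict

_ENUMERATION_LIMIT = 14  # enumerate all coalitions up to 2^14 - 2 rows


@dataclasses.dataclass
class ShapExplanation:
    compound_id: str | None
    task_id: str | None
    base_value: float              # expected model output over the background
    contributions: np.ndarray      # signed per-bit values, fingerprint length
    prediction: float              # model output for the compound

    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + float(self.contributions.sum())
                   - self.prediction)


def _as_predict_fn(model, task_id):
    if isinstance(model, TrainedModel):
        return lambda X: np.asarray(
            _model_predict(model, X, task_id=task_id)
        ).reshape(len(X))
    if callable(model):
        return lambda X: np.asarray(model(X)).reshape(len(X))
    raise TypeError("model must be a TrainedModel or a callable")


def _kernel_weight(d: int, s: int) -> float:
    # Shapley kernel pi(s) = (d - 1) / (C(d, s) * s * (d - s))
    from math import comb
    return (d - 1) / (comb(d, s) * s * (d - s))


def _coalitions(d: int, n_samples: int, rng: np.random.Generator):
    """Coalition matrix Z over d varying features plus regression weights.

    All 2^d - 2 proper coalitions are enumerated when they fit the
    budget; otherwise coalition sizes are sampled proportionally to the
    Shapley kernel and subsets uniformly within each size (uniform
    regression weights then approximate the kernel-weighted problem).
    """
    total = 2 ** d - 2
    if d <= _ENUMERATION_LIMIT and total <= max(n_samples, total):
        Z = np.zeros((total, d), dtype=np.int8)
        w = np.empty(total)
        row = 0
        for s in range(1, d):
            for subset in itertools.combinations(range(d), s):
                Z[row, list(subset)] = 1
                w[row] = _kernel_weight(d, s)
                row += 1
        return Z, w
    # antithetic sampling: each coalition is paired with its complement,
    # which has the same kernel weight and cancels much estimator noise
    half = max(n_samples // 2, 1)
    sizes = np.arange(1, d)
    p = (d - 1) / (sizes * (d - sizes))
    p = p / p.sum()
    chosen = rng.choice(sizes, size=half, p=p)
    Z = np.zeros((2 * half, d), dtype=np.int8)
    for i, s in enumerate(chosen):
        Z[2 * i, rng.choice(d, size=s, replace=False)] = 1
        Z[2 * i + 1] = 1 - Z[2 * i]
    return Z, np.ones(2 * half)


def kernel_shap(
    model,
    task_id: str | None,
    fingerprint: np.ndarray,
    background: np.ndarray,
    n_samples: int = 2048,
    seed: int = 0,
    compound_id: str | None = None,
) -> ShapExplanation:
    """Kernel SHAP estimate for one compound on one task.

    ``model`` may be a TrainedModel or any callable mapping an (n, M)
    array to n outputs.  Bits identical between the compound and every
    background row provably contribute nothing and are assigned zero;
    the remainder are solved by constrained weighted least squares, so
    local accuracy holds exactly.
    """
    f = _as_predict_fn(model, task_id)
    x = np.asarray(fingerprint, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if bg.shape[1] != x.shape[0]:
        raise ValueError("background and fingerprint lengths differ")
    rng = np.random.default_rng(seed)

    fx = float(f(x[None, :])[0])
    base = float(f(bg).mean())
    phi = np.zeros_like(x)

    varying = np.where((bg != x[None, :]).any(axis=0))[0]
    d = len(varying)
    if d == 0:
        return ShapExplanation(compound_id, task_id, base, phi, fx)
    if d == 1:
        phi[varying[0]] = fx - base
        return ShapExplanation(compound_id, task_id, base, phi, fx)
    if 2 ** d - 2 > n_samples and n_samples < d + 2:
        raise ValueError(
            f"n_samples={n_samples} too small for {d} varying features"
        )

    Z, w = _coalitions(d, n_samples, rng)

    # v(z): model output with coalition bits from x, the rest marginalized
    # over the background; evaluated in chunks to bound memory.
    v = np.empty(len(Z))
    B = bg.shape[0]
    chunk = max(1, 2 ** 22 // (B * x.shape[0] + 1))
    for start in range(0, len(Z), chunk):
        zc = Z[start:start + chunk]
        Xs = np.repeat(bg[None, :, :], len(zc), axis=0)          # (c, B, M)
        sel = zc.astype(bool)                                     # (c, d)
        for j, col in enumerate(varying):
            Xs[sel[:, j], :, col] = x[col]
        out = f(Xs.reshape(-1, x.shape[0]))
        v[start:start + chunk] = out.reshape(len(zc), B).mean(axis=1)

    # constrained WLS: eliminate the last varying feature so that
    # sum(phi) = fx - base holds by construction.
    y = v - base - Z[:, -1] * (fx - base)
    A = Z[:, :-1].astype(float) - Z[:, [-1]].astype(float)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    phi_v = np.empty(d)
    phi_v[:-1] = coef
    phi_v[-1] = (fx - base) - coef.sum()
    phi[varying] = phi_v
    return ShapExplanation(compound_id, task_id, base, phi, fx)


@dataclasses.dataclass
class GlobalSummary:
    """Per-(task, bit) attribution statistics and top-m rankings."""

    table: pd.DataFrame      # task_id, bit, mean_abs, mean_signed,
                             # mean_present, mean_absent, n
    m: int

    def top_bits(self, task_id: str) -> list[int]:
        sub = self.table[
            (self.table["task_id"] == task_id) & (self.table["mean_abs"] > 0)
        ]
        sub = sub.sort_values(["mean_abs", "bit"], ascending=[False, True])
        return sub["bit"].head(self.m).tolist()

    def ranking(self, task_id: str) -> pd.Series:
        """All bits of a task ordered by mean |contribution| descending."""
        sub = self.table[self.table["task_id"] == task_id]
        return sub.sort_values(["mean_abs", "bit"], ascending=[False, True]
                               ).set_index("bit")["mean_abs"]


def global_summary(
    explanations: Sequence[ShapExplanation],
    fingerprints: dict | None = None,
    m: int = 20,
) -> GlobalSummary:
    """Aggregate explanations into per-task mean |SHAP| per bit.

    ``fingerprints`` optionally maps compound_id to the bit vector so
    the presence/absence-conditioned means (contribution when the bit is
    set vs unset) can be reported.
    """
    if not explanations:
        raise ValueError("no explanations to summarize")
    by_task: dict[str, list[ShapExplanation]] = {}
    for e in explanations:
        by_task.setdefault(e.task_id, []).append(e)
    rows = []
    for tid, group in sorted(by_task.items(), key=lambda kv: str(kv[0])):
        C = np.stack([e.contributions for e in group])     # (n, M)
        present = None
        if fingerprints is not None:
            present = np.stack([
                np.asarray(fingerprints[e.compound_id], dtype=bool)
                for e in group
            ])
        for bit in range(C.shape[1]):
            col = C[:, bit]
            row = dict(task_id=tid, bit=bit,
                       mean_abs=float(np.abs(col).mean()),
                       mean_signed=float(col.mean()), n=len(col))
            if present is not None:
                p = present[:, bit]
                row["mean_present"] = float(col[p].mean()) if p.any() else np.nan
                row["mean_absent"] = float(col[~p].mean()) if (~p).any() else np.nan
            rows.append(row)
    return GlobalSummary(table=pd.DataFrame(rows), m=m)


def map_bit_to_atoms(
    structure: str, bit: int, radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> list[tuple[int, ...]]:
    """All atom environments of the structure hashing to a fingerprint
    bit (hash collisions yield several environments, all returned).
    Raises for a bit that is not set."""
    mol = _mol(structure)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=False
    )
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetFingerprint(mol, additionalOutput=ao)
    info = ao.GetBitInfoMap()
    if bit not in info:
        raise ValueError(f"bit {bit} is not set for this structure")
    envs = []
    for atom, rad in info[bit]:
        if rad == 0:
            envs.append((atom,))
            continue
        bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, rad, atom)
        atoms = {atom}
        for b in bonds:
            bond = mol.GetBondWithIdx(b)
            atoms.add(bond.GetBeginAtomIdx())
            atoms.add(bond.GetEndAtomIdx())
        envs.append(tuple(sorted(atoms)))
    return envs


@dataclasses.dataclass
class CompoundReport:
    """Per-task explanations of one compound plus the atom-level map of
    summed bit contributions (for substructure highlighting)."""

    compound_id: str
    structure: str
    explanations: dict[str, ShapExplanation]
    atom_contributions: dict[str, dict[int, float]]   # task -> atom -> value


def explain_compound(
    model: TrainedModel,
    structure: str,
    tasks: Sequence[str],
    background: np.ndarray,
    seed: int = 0,
    n_samples: int = 2048,
    compound_id: str | None = None,
    radius: int = DEFAULT_RADIUS,
) -> CompoundReport:
    """Explain one structure on each requested task and color its atoms
    by the summed contributions of the bits they participate in."""
    from .featurize import ecfp
    n_bits = model.n_bits
    fp = ecfp(structure, radius=radius, n_bits=n_bits)
    cid = compound_id or structure
    explanations: dict[str, ShapExplanation] = {}
    atom_maps: dict[str, dict[int, float]] = {}
    for tid in tasks:
        expl = kernel_shap(model, tid, fp.bits, background,
                           n_samples=n_samples, seed=seed, compound_id=cid)
        explanations[tid] = expl
        atoms: dict[int, float] = {}
        for bit in fp.on_bits:
            contrib = float(expl.contributions[bit])
            if contrib == 0.0:
                continue
            for env in map_bit_to_atoms(structure, bit, radius, n_bits):
                for a in env:
                    atoms[a] = atoms.get(a, 0.0) + contrib / len(env)
        atom_maps[tid] = atoms
    return CompoundReport(cid, structure, explanations, atom_maps)


def explanations_to_frame(
    explanations: Sequence[ShapExplanation],
) -> pd.DataFrame:
    """Long-format export: one row per nonzero (compound, task, bit)."""
    rows = []
    for e in explanations:
        for bit in np.nonzero(e.contributions)[0]:
            rows.append(dict(compound_id=e.compound_id, task_id=e.task_id,
                             bit=int(bit),
                             contribution=float(e.contributions[bit]),
                             base_value=e.base_value, prediction=e.prediction))
    return pd.DataFrame(
        rows, columns=["compound_id", "task_id", "bit", "contribution",
                       "base_value", "prediction"]
    )
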