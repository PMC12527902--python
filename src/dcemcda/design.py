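"""D-efficient paired choice-set design, blocking and questionnaire assembly.

The experimental design stage picks a small fraction of the 3^7 = 2187
possible profiles and pairs them into choice sets so that the multinomial
logit information matrix is as "large" as possible.  Design quality is the
D-error, det(I)^(-1/K); the search is coordinate exchange over one
attribute level at a time, restarted from several random designs.  The
opt-out alternative is not part of the optimized design; it is appended to
every task when questionnaires are assembled, together with one repeated
task used downstream as a consistency check.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .schema import AttributeSchema, Profile, encode_profile

__all__ = [
    "ChoiceSet",
    "ChoiceDesign",
    "Questionnaire",
    "DesignConfigurationError",
    "mnl_information_matrix",
    "d_error",
    "generate_defficient_design",
    "block_design",
    "build_questionnaire",
]

logger = logging.getLogger(__name__)


class DesignConfigurationError(ValueError):
    """Design request cannot be satisfied (identification or divisibility)."""


@dataclass(frozen=True)
class ChoiceSet:
    """One paired task: two generically labelled orphan-drug profiles."""

    alternatives: tuple[dict, dict]
    set_id: int

    def __post_init__(self) -> None:
        if dict(self.alternatives[0]) == dict(self.alternatives[1]):
            raise ValueError(f"set {self.set_id}: alternatives must differ")


@dataclass
class ChoiceDesign:
    sets: list[ChoiceSet]
    d_error: float
    prior: np.ndarray
    seed: int

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "d_error": self.d_error,
            "prior": np.asarray(self.prior, dtype=float).tolist(),
            "seed": self.seed,
            "sets": [
                {"set_id": s.set_id, "alternatives": [dict(a) for a in s.alternatives]}
                for s in self.sets
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ChoiceDesign":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        sets = [
            ChoiceSet(alternatives=(s["alternatives"][0], s["alternatives"][1]), set_id=s["set_id"])
            for s in payload["sets"]
        ]
        return cls(
            sets=sets,
            d_error=payload["d_error"],
            prior=np.asarray(payload["prior"], dtype=float),
            seed=payload["seed"],
        )


@dataclass
class Questionnaire:
    """An 11-task questionnaire: one block of 10 unique tasks plus a repeat.

    ``consistency_pair`` holds (position of the original task, position of
    its duplicate) in ``tasks``.  Every task implicitly offers an opt-out
    alternative in addition to the two drug profiles.
    """

    block_id: int
    tasks: list[ChoiceSet]
    consistency_pair: tuple[int, int]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def scored_positions(self) -> list[int]:
        """Task positions used for estimation (the duplicate is excluded)."""
        _, dup = self.consistency_pair
        return [p for p in range(self.n_tasks) if p != dup]


def _encode_design(design_sets: list[ChoiceSet], schema: AttributeSchema) -> np.ndarray:
    """(n_sets, 2, K) array of design vectors."""
    return np.asarray(
        [[encode_profile(a, schema) for a in s.alternatives] for s in design_sets], dtype=float
    )


def _set_information(x_set: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """One set's MNL information contribution: sum_j P_j (x_j - xbar)(x_j - xbar)^T."""
    v = x_set @ prior
    v = v - v.max()
    p = np.exp(v)
    p /= p.sum()
    xbar = p @ x_set
    centred = x_set - xbar
    return (centred * p[:, None]).T @ centred


def mnl_information_matrix(
    design: ChoiceDesign | list[ChoiceSet], prior: np.ndarray, schema: AttributeSchema
) -> np.ndarray:
    """Fisher information of the MNL model for a paired design under a prior.

    Returns the K x K matrix sum over sets of sum_j P_j (x_j - xbar)(x_j -
    xbar)^T, with choice probabilities computed from the prior coefficient
    vector (a zero prior makes every alternative equally likely).
    """
    sets = design.sets if isinstance(design, ChoiceDesign) else design
    k = schema.design_vector_length
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (k,):
        raise ValueError(f"prior must have length {k}, got shape {prior.shape}")
    x = _encode_design(sets, schema)
    info = np.zeros((k, k))
    for x_set in x:
        info += _set_information(x_set, prior)
    return info


def d_error(
    design: ChoiceDesign | list[ChoiceSet], prior: np.ndarray, schema: AttributeSchema
) -> float:
    """D-error det(I)^(-1/K); +inf when the information matrix is singular."""
    info = mnl_information_matrix(design, prior, schema)
    return _d_error_from_info(info)


def _d_error_from_info(info: np.ndarray) -> float:
    # eigenvalues rather than the raw determinant: a rank-deficient matrix
    # must read as singular even when floating-point det(I) is not exactly 0
    vals = np.linalg.eigvalsh(info)
    if vals[-1] <= 0 or vals[0] <= 1e-10 * vals[-1]:
        return math.inf
    return math.exp(-np.log(vals).mean())


def _random_profile(schema: AttributeSchema, rng: np.random.Generator) -> dict:
    return {a.name: int(rng.integers(a.n_levels)) for a in schema.attributes}


def _random_sets(schema: AttributeSchema, n_sets: int, rng: np.random.Generator) -> list[ChoiceSet]:
    sets = []
    for sid in range(n_sets):
        while True:
            p1, p2 = _random_profile(schema, rng), _random_profile(schema, rng)
            if p1 != p2:
                break
        sets.append(ChoiceSet(alternatives=(p1, p2), set_id=sid))
    return sets


def _dominates(p1: dict, p2: dict, schema: AttributeSchema) -> bool:
    """True if p1 is at least as good as p2 everywhere and better somewhere.

    Levels are ordered worst-to-best except continuous cost, where a lower
    numeric value is better.
    """
    better = False
    for a in schema.attributes:
        o1, o2 = p1[a.name], p2[a.name]
        if a.kind == "continuous":
            v1, v2 = a.level(o1).numeric_value, a.level(o2).numeric_value
            if v1 > v2:
                return False
            if v1 < v2:
                better = True
        else:
            if o1 < o2:
                return False
            if o1 > o2:
                better = True
    return better


def generate_defficient_design(
    schema: AttributeSchema,
    n_sets: int = 30,
    prior: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = 3,
    max_passes: int = 20,
) -> ChoiceDesign:
    """Coordinate-exchange search for a low D-error paired design.

    Starting from a random design, every (set, alternative, attribute)
    position is revisited in turn and the level that lowers the D-error is
    kept; passes repeat until no improvement, and the best design over
    ``n_restarts`` random starts is returned.  Deterministic under ``seed``.
    """
    k = schema.design_vector_length
    if prior is None:
        prior = np.zeros(k)
    prior = np.asarray(prior, dtype=float)
    if n_sets < k:
        raise DesignConfigurationError(
            f"{n_sets} paired sets cannot identify {k} parameters (need n_sets >= {k})"
        )
    master = np.random.default_rng(seed)
    best_sets: list[ChoiceSet] | None = None
    best_err = math.inf
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        sets = [
            [dict(a) for a in s.alternatives] for s in _random_sets(schema, n_sets, rng)
        ]
        x = np.asarray(
            [[encode_profile(p, schema) for p in pair] for pair in sets], dtype=float
        )
        contrib = np.asarray([_set_information(xs, prior) for xs in x])
        info = contrib.sum(axis=0)
        err = _d_error_from_info(info)
        for _pass in range(max_passes):
            improved = False
            for si in range(n_sets):
                for ai in range(2):
                    for attr in schema.attributes:
                        current = sets[si][ai][attr.name]
                        for lvl in range(attr.n_levels):
                            if lvl == current:
                                continue
                            candidate = dict(sets[si][ai])
                            candidate[attr.name] = lvl
                            other = sets[si][1 - ai]
                            if candidate == other:
                                continue
                            pair = [None, None]
                            pair[ai] = candidate
                            pair[1 - ai] = other
                            x_new = np.asarray(
                                [encode_profile(p, schema) for p in pair], dtype=float
                            )
                            new_contrib = _set_information(x_new, prior)
                            new_info = info - contrib[si] + new_contrib
                            new_err = _d_error_from_info(new_info)
                            if new_err < err:
                                sets[si][ai] = candidate
                                info = new_info
                                contrib[si] = new_contrib
                                err = new_err
                                current = lvl
                                improved = True
            if not improved:
                break
        if err < best_err:
            best_err = err
            best_sets = [
                ChoiceSet(alternatives=(pair[0], pair[1]), set_id=i)
                for i, pair in enumerate(sets)
            ]
    assert best_sets is not None
    for s in best_sets:
        if _dominates(s.alternatives[0], s.alternatives[1], schema) or _dominates(
            s.alternatives[1], s.alternatives[0], schema
        ):
            logger.warning("set %d contains a dominated alternative", s.set_id)
    return ChoiceDesign(sets=best_sets, d_error=best_err, prior=prior, seed=seed)


def block_design(
    design: ChoiceDesign, n_blocks: int = 3, seed: int = 0, n_sweeps: int = 50
) -> list[list[ChoiceSet]]:
    """Split a design into equal blocks balancing attribute-level frequencies.

    Starts from a seeded random equal split, then greedily swaps pairs of
    sets across blocks while the sum of squared deviations of per-block
    level frequencies from their across-block mean decreases.
    """
    n = design.n_sets
    if n % n_blocks != 0:
        raise DesignConfigurationError(f"{n} sets cannot be equally divided into {n_blocks} blocks")
    per = n // n_blocks
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    blocks = [[design.sets[i] for i in order[b * per : (b + 1) * per]] for b in range(n_blocks)]
    if n_sweeps == 0:
        return blocks
    return _improve_blocks(blocks, design, seed, n_sweeps)


def _improve_blocks(
    blocks: list[list[ChoiceSet]], design: ChoiceDesign, seed: int, n_sweeps: int
) -> list[list[ChoiceSet]]:
    # Level-frequency balance without needing the schema object: build the
    # level universe from the profiles themselves.
    names = sorted(blocks[0][0].alternatives[0].keys())
    n_levels = {
        nm: 1 + max(alt[nm] for b in blocks for s in b for alt in s.alternatives) for nm in names
    }

    def freqs(b: list[ChoiceSet]) -> np.ndarray:
        out = []
        for nm in names:
            c = np.zeros(n_levels[nm])
            for s in b:
                for alt in s.alternatives:
                    c[alt[nm]] += 1
            out.append(c)
        return np.concatenate(out)

    fmat = np.asarray([freqs(b) for b in blocks])

    def total(f: np.ndarray) -> float:
        return float(((f - f.mean(axis=0)) ** 2).sum())

    best = total(fmat)
    for _ in range(n_sweeps):
        improved = False
        for b1 in range(len(blocks)):
            for b2 in range(b1 + 1, len(blocks)):
                for i in range(len(blocks[b1])):
                    for j in range(len(blocks[b2])):
                        s1, s2 = blocks[b1][i], blocks[b2][j]
                        f1 = freqs([s2]) - freqs([s1])
                        trial = fmat.copy()
                        trial[b1] += f1
                        trial[b2] -= f1
                        t = total(trial)
                        if t < best - 1e-12:
                            blocks[b1][i], blocks[b2][j] = s2, s1
                            fmat = trial
                            best = t
                            improved = True
        if not improved:
            break
    return blocks


def build_questionnaire(
    block: list[ChoiceSet], repeat_index: int, seed: int = 0, block_id: int = 0
) -> Questionnaire:
    """Assemble one questionnaire: the block's tasks plus a consistency repeat.

    The task at ``repeat_index`` is duplicated and inserted at a seeded
    position at least two tasks after the original, giving 11 tasks for the
    default 10-set block.  Every task offers drug 1, drug 2 and opt-out.
    """
    if not block:
        raise ValueError("block is empty")
    n = len(block)
    if not 0 <= repeat_index < n:
        raise IndexError(f"repeat_index {repeat_index} out of range for block of {n}")
    candidates = list(range(repeat_index + 2, n + 1))
    if not candidates:
        raise DesignConfigurationError(
            "repeat task must be at least two positions before the end of the block"
        )
    rng = np.random.default_rng(seed)
    insert_at = int(candidates[rng.integers(len(candidates))])
    tasks = list(block)
    tasks.insert(insert_at, block[repeat_index])
    return Questionnaire(block_id=block_id, tasks=tasks, consistency_pair=(repeat_index, insert_at))


def export_questionnaire_csv(
    questionnaire: Questionnaire, schema: AttributeSchema, path: str | Path
) -> None:
    """Human-readable export: one row per task x alternative with level labels."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task", "alternative"] + schema.attribute_names)
        for pos, task in enumerate(questionnaire.tasks):
            for alt_no, alt in enumerate(task.alternatives, start=1):
                labels = [schema.attribute(nm).level(alt[nm]).label for nm in schema.attribute_names]
                writer.writerow([pos + 1, f"Orphan Drug {alt_no}"] + labels)
            writer.writerow([pos + 1, "Opt-out"] + [""] * len(schema.attribute_names))
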