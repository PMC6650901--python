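"""Transition-rule tables (the genome of the evolutionary search).

Each rule is six numbers.  The first five are the *condition*: the moduli of
three gradient vectors at window sizes 3/5/7 and the angles of the size-5 and
size-7 vectors relative to the size-3 vector (whose angle is fixed at 0 — the
representation is defined only up to rotation and reflection).  The sixth is
the *action*: the angle, relative to the matched rotation, along which the
cell's state is averaged with its neighbors.

Moduli live in ``[0, 2]``; angles in ``[0, 2*pi)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RuleSet", "MODULUS_BOUNDS", "ANGLE_BOUNDS", "PARAMS_PER_RULE"]

PARAMS_PER_RULE = 6
MODULUS_BOUNDS = (0.0, 2.0)
ANGLE_BOUNDS = (0.0, 2.0 * np.pi)

#: per-column (modulus3, modulus5, modulus7, angle5, angle7, action) flags
_IS_ANGLE = np.array([False, False, False, True, True, True])


@dataclass
class RuleSet:
    """An ``M x 6`` table of transition rules.

    Columns: ``|Gr3|, |Gr5|, |Gr7|, phi_r5, phi_r7, theta_r``.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != PARAMS_PER_RULE:
            raise ValueError(f"rule table must be M x 6, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("rule set must contain at least one rule")
        self.table = arr

    @property
    def n_rules(self) -> int:
        return self.table.shape[0]

    @property
    def genome_length(self) -> int:
        return self.table.size

    # -- genome view ---------------------------------------------------------

    def to_genome(self) -> np.ndarray:
        """Flatten to a length-6M vector (row-major: rule-by-rule)."""
        return self.table.ravel().copy()

    @classmethod
    def from_genome(cls, genome: np.ndarray) -> "RuleSet":
        g = np.asarray(genome, dtype=np.float64).ravel()
        if g.size % PARAMS_PER_RULE:
            raise ValueError(f"genome length {g.size} is not a multiple of 6")
        return cls(g.reshape(-1, PARAMS_PER_RULE))

    # -- bounds --------------------------------------------------------------

    @staticmethod
    def lower_bounds(n_rules: int) -> np.ndarray:
        lo = np.where(_IS_ANGLE, ANGLE_BOUNDS[0], MODULUS_BOUNDS[0])
        return np.tile(lo, n_rules)

    @staticmethod
    def upper_bounds(n_rules: int) -> np.ndarray:
        hi = np.where(_IS_ANGLE, ANGLE_BOUNDS[1], MODULUS_BOUNDS[1])
        return np.tile(hi, n_rules)

    @staticmethod
    def repair_genome(genome: np.ndarray) -> np.ndarray:
        """Clip moduli into [0, 2]; wrap angles modulo 2*pi (circular)."""
        g = np.asarray(genome, dtype=np.float64).reshape(-1, PARAMS_PER_RULE).copy()
        g[:, :3] = np.clip(g[:, :3], *MODULUS_BOUNDS)
        g[:, 3:] = np.mod(g[:, 3:], ANGLE_BOUNDS[1])
        return g.ravel()

    def within_bounds(self) -> bool:
        t = self.table
        mod_ok = (t[:, :3] >= MODULUS_BOUNDS[0]).all() and (t[:, :3] <= MODULUS_BOUNDS[1]).all()
        ang_ok = (t[:, 3:] >= ANGLE_BOUNDS[0]).all() and (t[:, 3:] <= ANGLE_BOUNDS[1]).all()
        return bool(mod_ok and ang_ok)

    # -- condition geometry --------------------------------------------------

    def condition_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """The three condition gradient vectors of each rule.

        Returns ``(vx, vy)`` of shape ``(M, 3)``: columns are window sizes
        3, 5, 7; the size-3 vector points along +x by construction.
        """
        t = self.table
        angles = np.column_stack([np.zeros(self.n_rules), t[:, 3], t[:, 4]])
        moduli = t[:, :3]
        return moduli * np.cos(angles), moduli * np.sin(angles)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rules": self.table.tolist(),
            "bounds": {"modulus": list(MODULUS_BOUNDS), "angle": list(ANGLE_BOUNDS)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        payload = json.loads(Path(path).read_text())
        if "rules" not in payload:
            raise ValueError(f"{path}: rule-set JSON is missing the 'rules' field")
        return cls(np.asarray(payload["rules"], dtype=np.float64))

    @classmethod
    def random(cls, n_rules: int, rng: np.random.Generator) -> "RuleSet":
        """Rules drawn uniformly over the parameter bounds."""
        g = rng.uniform(cls.lower_bounds(n_rules), cls.upper_bounds(n_rules))
        return cls.from_genome(g)
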