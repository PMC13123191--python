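"""Synthetic molecular datasets and score matrices with known structure.

The molecule generator enumerates valid SMILES from closed-form parametric
templates (alkyl chains, substituted benzenes and heteroaromatics, fused
ring cores), so every generated structure passes standardization without
rejection sampling and the Bemis-Murcko scaffold family of each molecule is
known by construction.  Targets follow a declared rule — linear in heavy
atom count, constant, or a classification margin on heavy atom count —
plus Gaussian noise, so the achievable error floor is known exactly.

The score-matrix generator produces additive contender-effect + block-effect
+ noise matrices for exercising the statistical comparison cascade, with an
optional heteroscedastic contender (noise scaled 5x) to trip Levene's test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .resample import METRICS, Metric, ScoreMatrix

__all__ = ["SyntheticSpec", "gen_molecules", "gen_score_matrix"]

# Scaffold-family templates: each maps a chain length m >= 1 to a valid
# SMILES whose Murcko scaffold is constant within the family.
_TEMPLATES = [
    ("alkane", lambda m: "C" * (m + 1)),            # acyclic: empty scaffold
    ("benzene", lambda m: "C" * m + "c1ccccc1"),
    ("naphthalene", lambda m: "C" * m + "c1ccc2ccccc2c1"),
    ("pyridine", lambda m: "C" * m + "c1ccccn1"),
    ("cyclohexane", lambda m: "C" * m + "C1CCCCC1"),
    ("furan", lambda m: "C" * m + "c1ccco1"),
    ("indole", lambda m: "C" * m + "c1ccc2[nH]ccc2c1"),
    ("thiophene", lambda m: "C" * m + "c1cccs1"),
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset; identical specs give identical data.

    ``scaffold_families`` is the number of distinct scaffold families (<= 8
    templates available); ``family_sizes`` optionally fixes per-family
    counts, otherwise molecules are distributed as evenly as possible.
    ``noise_sd`` is the Gaussian noise on the regression target (in target
    units); the linear rule is y = heavy_atom_count + noise, so no model can
    beat an RMSE floor of about ``noise_sd``.
    """

    n_molecules: int = 100
    scaffold_families: int = 3
    family_sizes: tuple[int, ...] | None = None
    target_rule: str = "linear_in_descriptor"  # | constant | classification_margin
    noise_sd: float = 0.5
    class_balance: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        if not 1 <= self.scaffold_families <= len(_TEMPLATES):
            raise ConfigurationError(
                f"scaffold_families must be in [1, {len(_TEMPLATES)}]"
            )
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.scaffold_families:
                raise ConfigurationError("family_sizes length must match families")
            if sum(self.family_sizes) != self.n_molecules:
                raise ConfigurationError("family_sizes must sum to n_molecules")
            if min(self.family_sizes) < 1:
                raise ConfigurationError("family sizes must be positive")
        if self.target_rule not in (
            "linear_in_descriptor", "constant", "classification_margin",
        ):
            raise ConfigurationError(f"unknown target_rule {self.target_rule!r}")


def gen_molecules(spec: SyntheticSpec, csv_path: str | Path | None = None) -> pd.DataFrame:
    """Generate the dataset as a DataFrame (id, smiles, family, target);
    optionally also written as CSV in the ingestion dialect."""
    rng = np.random.default_rng(spec.seed)
    if spec.family_sizes is not None:
        sizes = list(spec.family_sizes)
    else:
        base = spec.n_molecules // spec.scaffold_families
        sizes = [base] * spec.scaffold_families
        for i in range(spec.n_molecules - base * spec.scaffold_families):
            sizes[i] += 1
    rows = []
    for fam_idx, size in enumerate(sizes):
        name, make = _TEMPLATES[fam_idx]
        for m in range(1, size + 1):
            smiles = make(m)
            rows.append({"family": name, "smiles": smiles})
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"mol{i}" for i in range(len(df))])
    heavy = np.array(
        [Chem.MolFromSmiles(s).GetNumHeavyAtoms() for s in df["smiles"]], float
    )
    noise = rng.normal(0.0, spec.noise_sd, len(df))
    if spec.target_rule == "linear_in_descriptor":
        df["target"] = heavy + noise
    elif spec.target_rule == "constant":
        df["target"] = 1.0 + noise
    else:
        cut = np.quantile(heavy + noise, 1.0 - spec.class_balance)
        df["target"] = ((heavy + noise) > cut).astype(int)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def gen_score_matrix(
    n_blocks: int,
    contenders: list[str],
    effect_sizes: list[float],
    noise_sd: float = 0.05,
    hetero: bool = False,
    seed: int = 42,
    metric_name: str = "r2",
    block_sd: float = 0.05,
) -> ScoreMatrix:
    """Additive synthetic score matrix: contender effect + block effect +
    Gaussian noise.  ``hetero`` multiplies the last contender's noise by 5
    to induce variance heterogeneity."""
    if len(effect_sizes) != len(contenders):
        raise ConfigurationError("effect_sizes length must equal contenders")
    rng = np.random.default_rng(seed)
    block_eff = rng.normal(0.0, block_sd, n_blocks)
    mat = np.empty((n_blocks, len(contenders)))
    for j, eff in enumerate(effect_sizes):
        sd = noise_sd * (5.0 if (hetero and j == len(contenders) - 1) else 1.0)
        mat[:, j] = eff + block_eff + rng.normal(0.0, sd, n_blocks)
    index = pd.MultiIndex.from_tuples(
        [(b, 0) for b in range(n_blocks)], names=["fold", "repeat"]
    )
    scores = pd.DataFrame(mat, index=index, columns=list(contenders))
    return ScoreMatrix(list(contenders), METRICS[metric_name], scores)
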