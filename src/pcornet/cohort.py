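"""Seeded synthetic-cohort generation via a latent Gaussian copula.

The study's raw data are not publicly deposited, so every stage of the
pipeline can be driven by simulated cohorts that reproduce the published
marginal structure (means/SDs for continuous variables, level frequencies
for the categorical ones) and a three-block latent correlation structure:
a glycemic block (insulin, glucose, HOMA-IR), a lipid block (total
cholesterol, TAG) and a psychosocial block holding the remaining nodes.

Mixed types come from a single latent multivariate normal: continuous
columns are affine maps of their latent coordinate, categorical columns
are obtained by thresholding the latent normal at the quantiles of the
cumulative level frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .clinical import homa_ir
from .schema import (
    NODE_ORDER,
    VariableSpec,
    default_schema,
    validate_schema,
)

#: Relative floor applied to strictly positive biomarkers: a Gaussian draw
#: below 1% of the variable's mean is clamped there rather than resampled,
#: which keeps the generator a pure deterministic map of the seed.
POSITIVE_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic cohort draw.

    ``within_block_rho``/``between_block_rho`` are the latent correlations
    for same-block and cross-block variable pairs. ``homa_mode`` selects
    whether the HOMA-IR column is recomputed row-wise from the sampled
    insulin and glucose (``"formula"``, internally consistent) or sampled
    from its own published moments (``"sampled"``, which matches the
    printed HOMA-IR mean/SD but is incompatible with the formula given the
    printed insulin and glucose means).
    """

    n: int = 188
    schema: tuple[VariableSpec, ...] = field(
        default_factory=lambda: tuple(default_schema())
    )
    within_block_rho: float = 0.6
    between_block_rho: float = 0.05
    homa_mode: str = "formula"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError(
                f"n must be >= 20 so partial-correlation p-values have "
                f"positive degrees of freedom, got {self.n}"
            )
        for rho in (self.within_block_rho, self.between_block_rho):
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1, got {rho}")
        if self.homa_mode not in ("formula", "sampled"):
            raise ValueError(f"homa_mode must be 'formula' or 'sampled', "
                             f"got {self.homa_mode!r}")
        validate_schema(list(self.schema))


@dataclass
class CohortTable:
    """An N x 17 cohort in native units plus its variable schema."""

    frame: pd.DataFrame
    schema: list[VariableSpec]

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def validate(self) -> None:
        """Check type-level invariants of every column."""
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()].tolist()
            raise ValueError(f"missing cells in columns {bad}")
        by_name = {s.name: s for s in self.schema}
        for col in self.frame.columns:
            spec = by_name[col]
            vals = self.frame[col].to_numpy()
            if spec.vartype in ("binary", "ordinal"):
                levels = set(range(spec.n_levels))
                seen = set(np.unique(vals).astype(int))
                if not seen <= levels:
                    raise ValueError(
                        f"{col}: values {sorted(seen - levels)} outside coded "
                        f"levels {sorted(levels)}"
                    )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")

    def schema_to_yaml(self, path: str | Path) -> None:
        payload = [s.to_dict() for s in self.schema]
        Path(path).write_text(
            yaml.safe_dump(payload, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_csv(cls, path: str | Path,
                 schema: list[VariableSpec] | None = None) -> "CohortTable":
        """Read a cohort CSV with the 17 standard column labels.

        Raises with the offending column/row named when the file does not
        match the expected schema or contains a non-numeric cell.
        """
        frame = pd.read_csv(path)
        missing = [c for c in NODE_ORDER if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort CSV is missing columns {missing}")
        frame = frame[list(NODE_ORDER)]
        for col in frame.columns:
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric cell at row {row}, column {col!r}: "
                    f"{frame[col].iloc[row]!r}"
                )
            if converted.isna().any():
                row = int(np.flatnonzero(converted.isna().to_numpy())[0])
                raise ValueError(f"missing cell at row {row}, column {col!r}")
            frame[col] = converted
        return cls(frame=frame, schema=schema or default_schema())


def _block_index(schema: list[VariableSpec]) -> list[str]:
    return [s.block for s in schema]


def latent_correlation(config: GeneratorConfig) -> np.ndarray:
    """Latent correlation matrix implied by the block design.

    Raises
    ------
    ValueError
        If the implied matrix is not positive definite; the message names
        the offending within/between correlations.
    """
    blocks = _block_index(list(config.schema))
    p = len(blocks)
    corr = np.full((p, p), config.between_block_rho)
    for i in range(p):
        for j in range(p):
            if blocks[i] == blocks[j]:
                corr[i, j] = config.within_block_rho
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"latent correlation matrix is not positive definite for "
            f"within_block_rho={config.within_block_rho}, "
            f"between_block_rho={config.between_block_rho}"
        ) from None
    return corr


def _map_marginal(z: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Map one standard-normal latent column to its native marginal."""
    if spec.vartype == "continuous":
        x = spec.mean + spec.sd * z
        if spec.positive:
            x = np.maximum(x, POSITIVE_FLOOR_FRACTION * abs(spec.mean))
        return x
    # Quantile thresholding: latent below the q-th cumulative-normal
    # threshold lands in category q.
    cum = np.cumsum(spec.category_probs)[:-1]
    thresholds = stats.norm.ppf(cum)
    return np.searchsorted(thresholds, z, side="left").astype(float)


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a seeded synthetic cohort.

    The same config (including seed) always yields a bit-identical table.
    """
    schema = list(config.schema)
    corr = latent_correlation(config)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n, len(schema))) @ chol.T

    columns = {
        spec.name: _map_marginal(z[:, j], spec)
        for j, spec in enumerate(schema)
    }
    frame = pd.DataFrame(columns, columns=[s.name for s in schema])
    frame = frame[list(NODE_ORDER)]

    if config.homa_mode == "formula":
        frame["HOMA"] = homa_ir(frame["Insulin"].to_numpy(),
                                frame["Glucose"].to_numpy())

    table = CohortTable(frame=frame, schema=schema)
    table.validate()
    return table
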