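"""Variable schema for the 17-node health cohort.

The cohort couples four measurement dimensions — sociodemographic
(sex, age, marital status, social position), nutritional patterns
(three factor-analytic diet scores), physical/cardiometabolic
(BMI, hypertension, glucose, insulin, total cholesterol,
triacylglycerol, HOMA-IR) and psychological (depression, anxiety,
stress) — into a single mixed-type table whose conditional-dependence
structure is the object of analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: Canonical column order used throughout the package.
NODE_ORDER: tuple[str, ...] = (
    "Sex", "Age", "Marital", "Social", "NP1", "NP2", "NP3",
    "BMI", "HTN", "Glucose", "Insulin", "CholesT", "TAG", "HOMA",
    "Depre", "Anxiety", "Stress",
)

#: Measurement dimension of each variable (used for export colouring/tagging).
DIMENSIONS: dict[str, str] = {
    "Sex": "sociodemographic", "Age": "sociodemographic",
    "Marital": "sociodemographic", "Social": "sociodemographic",
    "NP1": "nutritional", "NP2": "nutritional", "NP3": "nutritional",
    "BMI": "physical", "HTN": "physical", "Glucose": "physical",
    "Insulin": "physical", "CholesT": "physical", "TAG": "physical",
    "HOMA": "physical",
    "Depre": "psychological", "Anxiety": "psychological",
    "Stress": "psychological",
}

#: Correlation blocks of the simulator's latent Gaussian: a glycemic block
#: (insulin, glucose, HOMA-IR), a lipid block (total cholesterol, TAG) and a
#: residual psychosocial block holding everything else.
BLOCKS: dict[str, str] = {
    "Glucose": "metabolic_glycemic", "Insulin": "metabolic_glycemic",
    "HOMA": "metabolic_glycemic",
    "CholesT": "lipid", "TAG": "lipid",
}

VALID_VARTYPES = ("continuous", "binary", "ordinal")


@dataclass(frozen=True)
class VariableSpec:
    """Marginal specification of one cohort variable.

    Parameters
    ----------
    name : str
        Variable label (one of :data:`NODE_ORDER` for the default cohort).
    vartype : {"continuous", "binary", "ordinal"}
        Measurement type. Continuous variables are parameterised by
        ``mean``/``sd`` in native units; binary/ordinal by a probability
        vector over coded levels ``0, 1, ...``.
    mean, sd : float, optional
        Location and scale for continuous variables.
    category_probs : tuple of float, optional
        Level frequencies for binary/ordinal variables; must sum to 1.
    block : str
        Latent-correlation block the variable belongs to.
    positive : bool
        Whether the quantity is strictly positive in nature (biomarkers,
        age, questionnaire totals); the simulator floors such draws.
    """

    name: str
    vartype: str
    mean: float | None = None
    sd: float | None = None
    category_probs: tuple[float, ...] | None = None
    block: str = "psychosocial"
    positive: bool = False

    def __post_init__(self) -> None:
        if self.vartype not in VALID_VARTYPES:
            raise ValueError(f"{self.name}: unknown vartype {self.vartype!r}")
        if self.vartype == "continuous":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: continuous spec needs mean and sd")
            if not self.sd > 0:
                raise ValueError(f"{self.name}: sd must be > 0, got {self.sd}")
        else:
            if self.category_probs is None:
                raise ValueError(f"{self.name}: categorical spec needs category_probs")
            total = math.fsum(self.category_probs)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"{self.name}: category_probs sum to {total!r}, expected 1"
                )
            if self.vartype == "binary" and len(self.category_probs) != 2:
                raise ValueError(f"{self.name}: binary spec needs exactly 2 probs")
            if any(p < 0 for p in self.category_probs):
                raise ValueError(f"{self.name}: negative category probability")

    @property
    def n_levels(self) -> int:
        if self.category_probs is None:
            raise ValueError(f"{self.name} is continuous")
        return len(self.category_probs)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "vartype": self.vartype, "block": self.block,
                   "positive": self.positive}
        if self.vartype == "continuous":
            d["mean"] = self.mean
            d["sd"] = self.sd
        else:
            d["category_probs"] = list(self.category_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        d = dict(d)
        if "category_probs" in d and d["category_probs"] is not None:
            d["category_probs"] = tuple(d["category_probs"])
        return cls(**d)


def default_schema() -> list[VariableSpec]:
    """Default 17-variable schema of the high-weight young-adult cohort.

    Continuous means/SDs are the cohort descriptives (age 20.8 y,
    BMI 28.4 kg/m2, glucose 147.80 mg/dL, insulin 2.54 uIU/mL, total
    cholesterol 5.89 mmol/L, TAG 5.21 mmol/L, HOMA-IR 10.69, DASS-derived
    depression/anxiety/stress scores); the three nutritional-pattern scores
    are standardised to mean 0, SD 1. Category frequencies are stored as
    exact count fractions of the N=188 cohort (e.g. 81/188 women,
    48/188 hypertensive) so that probability vectors sum to one exactly.
    """
    n = 188.0
    return [
        VariableSpec("Sex", "binary", category_probs=(107 / n, 81 / n)),
        VariableSpec("Age", "continuous", mean=20.8, sd=2.6, positive=True),
        VariableSpec("Marital", "ordinal", category_probs=(148 / n, 35 / n, 5 / n)),
        VariableSpec("Social", "ordinal", category_probs=(71 / n, 62 / n, 55 / n)),
        VariableSpec("NP1", "continuous", mean=0.0, sd=1.0),
        VariableSpec("NP2", "continuous", mean=0.0, sd=1.0),
        VariableSpec("NP3", "continuous", mean=0.0, sd=1.0),
        VariableSpec("BMI", "continuous", mean=28.4, sd=2.9, positive=True),
        VariableSpec("HTN", "binary", category_probs=(140 / n, 48 / n)),
        VariableSpec("Glucose", "continuous", mean=147.80, sd=52.43,
                     block="metabolic_glycemic", positive=True),
        VariableSpec("Insulin", "continuous", mean=2.54, sd=0.78,
                     block="metabolic_glycemic", positive=True),
        VariableSpec("CholesT", "continuous", mean=5.89, sd=1.30,
                     block="lipid", positive=True),
        VariableSpec("TAG", "continuous", mean=5.21, sd=1.55,
                     block="lipid", positive=True),
        VariableSpec("HOMA", "continuous", mean=10.69, sd=2.62,
                     block="metabolic_glycemic", positive=True),
        VariableSpec("Depre", "continuous", mean=98.9, sd=11.2, positive=True),
        VariableSpec("Anxiety", "continuous", mean=10.4, sd=2.9, positive=True),
        VariableSpec("Stress", "continuous", mean=193.2, sd=52.1, positive=True),
    ]


def validate_schema(schema: list[VariableSpec]) -> None:
    """Require each of the 17 study variables to appear exactly once."""
    names = [s.name for s in schema]
    if sorted(names) != sorted(NODE_ORDER):
        missing = set(NODE_ORDER) - set(names)
        extra = set(names) - set(NODE_ORDER)
        dupes = {x for x in names if names.count(x) > 1}
        raise ValueError(
            f"schema must contain the 17 study variables exactly once "
            f"(missing={sorted(missing)}, extra={sorted(extra)}, "
            f"duplicated={sorted(dupes)})"
        )
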