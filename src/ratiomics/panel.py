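"""Targeted-metabolomics panel specification.

Emulates a Biocrates-style flow-injection panel: eight chemical classes
(acylcarnitines, amino acids, biogenic amines, diacyl- and acyl-alkyl
phosphatidylcholines, lysophosphatidylcholines, sphingolipids, hexose)
with log-normal concentrations in correlated within-class blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASSES = (
    "acylcarnitine",
    "amino acid",
    "biogenic amine",
    "phosphatidylcholine-aa",
    "phosphatidylcholine-ae",
    "lysophosphatidylcholine",
    "sphingolipid",
    "sugar",
)

# Default class mix for a 135-metabolite quantified panel: 12 acylcarnitines,
# 21 amino acids, 8 biogenic amines, 69 phosphatidylcholines (38 aa + 31 ae),
# 11 lysoPCs, 13 sphingomyelins and hexose.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "acylcarnitine": 12 / 135,
    "amino acid": 21 / 135,
    "biogenic amine": 8 / 135,
    "phosphatidylcholine-aa": 38 / 135,
    "phosphatidylcholine-ae": 31 / 135,
    "lysophosphatidylcholine": 11 / 135,
    "sphingolipid": 13 / 135,
    "sugar": 1 / 135,
}

# Typical log-scale (natural log of µmol/l) location and spread per class.
CLASS_LOG_MEAN: dict[str, float] = {
    "acylcarnitine": -1.5,
    "amino acid": 4.5,
    "biogenic amine": -0.5,
    "phosphatidylcholine-aa": 2.5,
    "phosphatidylcholine-ae": 0.5,
    "lysophosphatidylcholine": 2.0,
    "sphingolipid": 2.8,
    "sugar": 8.5,
}
CLASS_LOG_SD: dict[str, float] = {c: 0.35 for c in CLASSES}

# Ordered so that small panels still contain the branched-chain amino
# acids and the other ratio-relevant species.
_AMINO_ACIDS = [
    "Val", "Ala", "Gly", "Ser", "Gln", "Ile", "Leu", "Arg", "Asn", "Asp",
    "Cit", "Glu", "His", "Lys", "Met", "Orn", "Phe", "Pro", "Thr", "Trp",
    "Tyr",
]
_BIOGENIC_AMINES = [
    "ADMA", "Creatinine", "Kynurenine", "Putrescine", "Sarcosine",
    "Serotonin", "Taurine", "alpha-AAA", "SDMA", "Spermidine", "Spermine",
    "Histamine",
]
_ACYLCARNITINES = [
    "C0", "C2", "C3", "C4", "C5", "C8", "C10", "C12", "C14:1", "C16",
    "C18:1", "C18:2", "C6 (C4:1-DC)", "C10:1", "C14:2", "C16:1",
]
# Arginine-responsive lysoPC species (myristic, palmitic, palmitoleic,
# arachidonic acyl chains).
ARGININE_RESPONSIVE_LYSOPC = (
    "lysoPC a C14:0",
    "lysoPC a C16:0",
    "lysoPC a C16:1",
    "lysoPC a C20:4",
)
_LYSOPC = list(ARGININE_RESPONSIVE_LYSOPC) + [
    "lysoPC a C17:0", "lysoPC a C18:0", "lysoPC a C18:1", "lysoPC a C18:2",
    "lysoPC a C20:3", "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C28:0",
    "lysoPC a C26:1", "lysoPC a C28:1",
]


def _pc_names(prefix: str, n: int, must_have: tuple[str, ...] = ()) -> list[str]:
    names = list(must_have)
    for carbons in range(30, 46, 2):
        for bonds in range(0, 7):
            name = f"{prefix} C{carbons}:{bonds}"
            if name not in names:
                names.append(name)
            if len(names) >= n:
                return names[:n]
    raise ValueError(f"cannot generate {n} unique {prefix} names")


def _sm_names(n: int) -> list[str]:
    names = []
    for carbons in range(16, 27, 2):
        names.append(f"SM C{carbons}:0")
        names.append(f"SM C{carbons}:1")
        names.append(f"SM (OH) C{carbons}:1")
    return names[:n]


def _class_names(cls: str, n: int) -> list[str]:
    if cls == "amino acid":
        pool = _AMINO_ACIDS
    elif cls == "biogenic amine":
        pool = _BIOGENIC_AMINES
    elif cls == "acylcarnitine":
        pool = _ACYLCARNITINES
    elif cls == "phosphatidylcholine-aa":
        return _pc_names("PC aa", n, must_have=("PC aa C34:4", "PC aa C32:1"))
    elif cls == "phosphatidylcholine-ae":
        return _pc_names("PC ae", n, must_have=("PC ae C32:2", "PC ae C36:0"))
    elif cls == "lysophosphatidylcholine":
        pool = _LYSOPC
    elif cls == "sphingolipid":
        return _sm_names(n)
    elif cls == "sugar":
        pool = ["H1", "H2"]
    else:
        raise ValueError(f"unknown metabolite class: {cls}")
    if n > len(pool):
        pool = pool + [f"{pool[-1]}-x{i}" for i in range(n - len(pool))]
    return pool[:n]


@dataclass
class PanelSpec:
    """Metabolite panel: names, class labels and a log-scale covariance model.

    The covariance is block-structured: correlation ``within_class_corr``
    inside a chemical class, ``between_class_corr`` across classes, with
    optional per-pair overrides (used to plant a component-dilution
    correlation between a signal pair).
    """

    names: list[str]
    classes: list[str]
    log_means: dict[str, float] = field(default_factory=dict)
    log_sds: dict[str, float] = field(default_factory=dict)
    within_class_corr: float = 0.4
    between_class_corr: float = 0.1
    pair_corr_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("metabolite names must be unique")
        if len(self.names) != len(self.classes):
            raise ValueError("names and classes must align")
        if not (0 <= self.within_class_corr < 1):
            raise ValueError("within_class_corr must be in [0, 1)")
        if not self.log_means:
            self.log_means = {
                m: CLASS_LOG_MEAN[c] for m, c in zip(self.names, self.classes)
            }
        if not self.log_sds:
            self.log_sds = {
                m: CLASS_LOG_SD[c] for m, c in zip(self.names, self.classes)
            }
        # Fail fast on a non-positive-definite correlation request.
        self.log_covariance()

    @property
    def n_metabolites(self) -> int:
        return len(self.names)

    def class_of(self, name: str) -> str:
        return self.classes[self.names.index(name)]

    def members(self, cls: str) -> list[str]:
        return [m for m, c in zip(self.names, self.classes) if c == cls]

    def log_covariance(self) -> np.ndarray:
        """Positive-definite covariance of log-concentrations."""
        m = self.n_metabolites
        cls = np.asarray(self.classes)
        corr = np.where(
            cls[:, None] == cls[None, :], self.within_class_corr, self.between_class_corr
        )
        np.fill_diagonal(corr, 1.0)
        idx = {name: i for i, name in enumerate(self.names)}
        for (a, b), rho in self.pair_corr_overrides.items():
            i, j = idx[a], idx[b]
            corr[i, j] = corr[j, i] = rho
        sd = np.array([self.log_sds[name] for name in self.names])
        cov = corr * np.outer(sd, sd)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                "requested correlation structure is not positive definite; "
                "lower within/between-class or override correlations"
            ) from None
        assert cov.shape == (m, m)
        return cov

    def mean_vector(self) -> np.ndarray:
        return np.array([self.log_means[name] for name in self.names])


def make_panel(
    n_metabolites: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    within_class_corr: float = 0.4,
    between_class_corr: float = 0.1,
) -> PanelSpec:
    """Build a deterministic panel of ``n_metabolites`` across the eight classes.

    ``class_mix`` gives per-class proportions (must sum to 1); counts are
    apportioned by largest remainder so they total exactly ``n_metabolites``.
    """
    if n_metabolites < 2:
        raise ValueError("a panel needs at least 2 metabolites")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"class proportions must sum to 1, got {total}")
    raw = {c: n_metabolites * p for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_metabolites - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    names: list[str] = []
    classes: list[str] = []
    for cls in CLASSES:
        n_cls = counts.get(cls, 0)
        if n_cls == 0:
            continue
        names.extend(_class_names(cls, n_cls))
        classes.extend([cls] * n_cls)
    # seed currently only fixes the (deterministic) name layout; kept so the
    # panel builder's signature is stable if name sampling ever randomises.
    del seed
    return PanelSpec(
        names=names,
        classes=classes,
        within_class_corr=within_class_corr,
        between_class_corr=between_class_corr,
    )
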