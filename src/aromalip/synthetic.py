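"""Synthetic data with known ground truth for every pipeline stage.

No raw instrument data ship with dry-cured-ham flavor studies, so the
test surface is built on generators whose truth is known exactly:

* replicate GC-MS peak tables — per-compound true relative contents,
  log-normal replicate noise with a prescribed arithmetic CV, and
  Bernoulli detection dropout encoded as missing values;
* shorthand lipid tables — names drawn from the parser's own grammar
  with class-code frequencies set by a weight map;
* paired lipid/volatile blocks with planted Pearson correlations via a
  latent bivariate-normal construction.

Every generator takes an explicit seed and owns its own
``numpy.random.Generator``; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lipids as _lip

TOTAL_AREA = 1e6  # arbitrary summed true peak area of a simulated run


@dataclass
class SyntheticSpec:
    """Ground-truth description of a simulated replicate peak table.

    ``true_relative_content`` are proportions over compounds (sum 1);
    ``replicate_cv`` and ``dropout_prob`` may be scalars or per-compound
    arrays.  Four replicates mirror the four-ham sampling design of the
    study this emulates.
    """

    n_compounds: int
    n_replicates: int = 4
    true_relative_content: np.ndarray | None = None
    replicate_cv: float | np.ndarray = 0.15
    dropout_prob: float | np.ndarray = 0.0
    seed: int = 0
    threshold_assignment: dict[str, float] = field(default_factory=dict)
    compounds: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be a positive count")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive count")
        if self.true_relative_content is None:
            self.true_relative_content = np.full(
                self.n_compounds, 1.0 / self.n_compounds
            )
        self.true_relative_content = np.asarray(
            self.true_relative_content, dtype=float
        )
        if self.true_relative_content.shape != (self.n_compounds,):
            raise ValueError(
                "true_relative_content length must equal n_compounds"
            )
        if abs(self.true_relative_content.sum() - 1.0) > 1e-9:
            raise ValueError("true_relative_content must sum to 1")
        self.replicate_cv = np.broadcast_to(
            np.asarray(self.replicate_cv, dtype=float), (self.n_compounds,)
        ).copy()
        if (self.replicate_cv < 0).any():
            raise ValueError("replicate_cv must be >= 0")
        self.dropout_prob = np.broadcast_to(
            np.asarray(self.dropout_prob, dtype=float), (self.n_compounds,)
        ).copy()
        if ((self.dropout_prob < 0) | (self.dropout_prob > 1)).any():
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.compounds is None:
            width = len(str(self.n_compounds))
            self.compounds = [
                f"compound_{i + 1:0{width}d}" for i in range(self.n_compounds)
            ]
        if len(self.compounds) != self.n_compounds:
            raise ValueError("compounds length must equal n_compounds")


def generate_peak_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Simulate a compounds × replicates peak-area matrix.

    Detected areas are log-normal with arithmetic mean proportional to
    the true relative content and arithmetic CV equal to
    ``replicate_cv`` (σ² = ln(1+cv²), µ = ln mean − σ²/2); peak areas
    are positive and right-skewed, which the log-normal matches.
    Non-detections are NaN.
    """
    rng = np.random.default_rng(spec.seed)
    means = spec.true_relative_content * TOTAL_AREA
    cv = spec.replicate_cv
    sigma2 = np.log1p(cv**2)
    mu = np.where(means > 0, np.log(np.where(means > 0, means, 1.0)), -np.inf)
    mu = mu - sigma2 / 2.0
    shape = (spec.n_compounds, spec.n_replicates)
    z = rng.standard_normal(shape)
    areas = np.exp(mu[:, None] + np.sqrt(sigma2)[:, None] * z)
    areas[means == 0] = 0.0
    dropped = rng.random(shape) < spec.dropout_prob[:, None]
    areas[dropped] = np.nan
    return pd.DataFrame(
        areas,
        index=pd.Index(spec.compounds, name="compound"),
        columns=[f"rep_{j + 1}" for j in range(spec.n_replicates)],
    )


def _random_chain(rng: np.random.Generator, cls: str) -> _lip.Chain:
    carbons = int(rng.integers(8, 27))
    # typical acyl chains run 16:0 .. 22:6; cap unsaturation by length
    db_max = min(6, max(0, (carbons - 8) // 2))
    double_bonds = int(rng.integers(0, db_max + 1))
    ether = ""
    if cls in ("TG", "DG", "PC", "PE") and rng.random() < 0.15:
        ether = "O-" if rng.random() < 0.8 else "P-"
    oxy = 0
    if cls in ("SM", "Cer", "HexCer", "SHexCer", "PE-Cer") :
        oxy = int(rng.integers(1, 4))
    elif rng.random() < 0.05:
        oxy = int(rng.integers(1, 3))
    return _lip.Chain(carbons=carbons, double_bonds=double_bonds,
                      ether_prefix=ether, extra_oxygens=oxy)


_CHAINS_PER_CLASS = {
    "TG": 3, "DG": 2, "MG": 1, "DGCC": 2, "DGTS": 2, "MGDG": 2, "DGDG": 2,
    "PC": 2, "PE": 2, "PS": 2, "PI": 2, "PG": 2, "PA": 2,
    "SM": 2, "Cer": 2, "HexCer": 2, "SHexCer": 1, "PE-Cer": 2,
    "FA": 1, "FAHFA": 2, "NAGly": 2, "ST": 2, "CE": 1, "SE": 1, "PR": 1,
}


def _random_lipid_name(rng: np.random.Generator, cls: str) -> str:
    n_chains = _CHAINS_PER_CLASS.get(cls, 2)
    chains = tuple(_random_chain(rng, cls) for _ in range(n_chains))
    if n_chains == 1:
        c = chains[0]
        species = _lip.LipidSpecies(
            raw_name="", class_code=cls,
            category=_lip.categorize(cls), chains=(),
            sum_carbons=c.carbons, sum_double_bonds=c.double_bonds,
            sum_extra_oxygens=c.extra_oxygens, sn_positions_known=False,
            ether_prefix=c.ether_prefix,
        )
    else:
        species = _lip.LipidSpecies(
            raw_name="", class_code=cls,
            category=_lip.categorize(cls), chains=chains,
            sum_carbons=sum(c.carbons for c in chains),
            sum_double_bonds=sum(c.double_bonds for c in chains),
            sum_extra_oxygens=sum(c.extra_oxygens for c in chains),
            sn_positions_known=bool(rng.random() < 0.5),
        )
    return _lip.format_lipid(species)


def generate_lipid_table(
    n_species: int, subclass_weights: dict[str, float], seed: int = 0,
    n_samples: int = 4,
) -> pd.DataFrame:
    """Draw syntactically valid shorthand names with class frequencies set
    by ``subclass_weights``, plus log-normal relative abundances.

    Every generated name parses under the default registry; duplicate
    names are redrawn so the table index is unique.
    """
    unknown = sorted(set(subclass_weights) - set(_lip.DEFAULT_REGISTRY))
    if unknown:
        raise ValueError(
            f"unknown class codes in weights: {unknown}; valid codes: "
            f"{', '.join(sorted(_lip.DEFAULT_REGISTRY))}"
        )
    if n_species < 1:
        raise ValueError("n_species must be a positive count")
    rng = np.random.default_rng(seed)
    codes = sorted(subclass_weights)
    w = np.array([subclass_weights[c] for c in codes], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("subclass_weights must be non-negative, sum > 0")
    w = w / w.sum()
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n_species:
        cls = codes[int(rng.choice(len(codes), p=w))]
        name = _random_lipid_name(rng, cls)
        if name not in seen:
            seen.add(name)
            names.append(name)
    abundance = rng.lognormal(mean=0.0, sigma=1.0,
                              size=(n_species, n_samples))
    return pd.DataFrame(
        abundance,
        index=pd.Index(names, name="lipid"),
        columns=[f"sample_{j + 1}" for j in range(n_samples)],
    )


@dataclass(frozen=True)
class PlantedCorrelation:
    """A lipid/volatile feature pair with a target population Pearson r."""

    lipid_feature: str
    volatile_feature: str
    target_r: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError(
                f"target_r must lie in [-1, 1], got {self.target_r}"
            )


def generate_correlated_blocks(
    planted: list[PlantedCorrelation], n_samples: int, seed: int = 0,
    extra_lipids: int = 0, extra_volatiles: int = 0,
    loc: float = 100.0, scale: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two feature × sample blocks with planted cross-block correlations.

    Each planted pair is built from a latent bivariate standard normal
    with correlation exactly ``target_r`` and then mapped affinely to
    ``loc + scale·z``, so the population Pearson correlation equals the
    target (an affine map preserves r).  All other feature pairs are
    independent.  Extra features are pure noise.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    lip_names = [p.lipid_feature for p in planted]
    vol_names = [p.volatile_feature for p in planted]
    if len(set(lip_names)) < len(lip_names) or len(set(vol_names)) < len(vol_names):
        raise ValueError("each feature may appear in at most one planted pair")
    rng = np.random.default_rng(seed)
    lip_rows, vol_rows = [], []
    for p in planted:
        za = rng.standard_normal(n_samples)
        eps = rng.standard_normal(n_samples)
        zb = p.target_r * za + np.sqrt(1.0 - p.target_r**2) * eps
        lip_rows.append(loc + scale * za)
        vol_rows.append(loc + scale * zb)
    for i in range(extra_lipids):
        lip_names.append(f"noise_lipid_{i + 1}")
        lip_rows.append(loc + scale * rng.standard_normal(n_samples))
    for i in range(extra_volatiles):
        vol_names.append(f"noise_volatile_{i + 1}")
        vol_rows.append(loc + scale * rng.standard_normal(n_samples))
    samples = [f"sample_{j + 1}" for j in range(n_samples)]
    lip = pd.DataFrame(np.array(lip_rows),
                       index=pd.Index(lip_names, name="lipid"),
                       columns=samples)
    vol = pd.DataFrame(np.array(vol_rows),
                       index=pd.Index(vol_names, name="compound"),
                       columns=samples)
    return lip, vol


#: Free amino-acid mean relative contents used by the default simulated
#: profile (same scale as the study's printed units).  L-alanine leads,
#: followed by L-lysine and L-valine; seven amino acids sit at or above
#: the key-selection cutoff of 40.
DEFAULT_AMINO_PROFILE: dict[str, float] = {
    "L-alanine": 120.0, "L-lysine": 95.0, "L-valine": 70.0,
    "L-glutamic acid": 55.0, "glycine": 48.0, "L-leucine": 44.0,
    "L-threonine": 40.0, "L-serine": 35.0, "L-proline": 32.0,
    "L-isoleucine": 28.0, "L-phenylalanine": 25.0, "L-methionine": 22.0,
    "L-histidine": 18.0, "L-arginine": 16.0, "L-tyrosine": 14.0,
    "L-tryptophan": 10.0, "L-glutamine": 9.0, "L-asparagine": 8.0,
    "L-aspartic acid": 7.0, "L-cysteine": 5.0, "L-ornithine": 4.0,
    "L-citrulline": 3.0, "4-aminobutyric acid": 2.5, "beta-alanine": 2.0,
}


def generate_amino_table(
    profile: dict[str, float] | None = None, cv: float = 0.1,
    n_samples: int = 4, seed: int = 0,
) -> pd.DataFrame:
    """Free amino-acid × sample relative contents, log-normal around a
    mean profile with arithmetic CV ``cv``."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    profile = DEFAULT_AMINO_PROFILE if profile is None else profile
    rng = np.random.default_rng(seed)
    names = list(profile)
    means = np.array([profile[n] for n in names], dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(means) - sigma2 / 2.0
    z = rng.standard_normal((len(names), n_samples))
    vals = np.exp(mu[:, None] + np.sqrt(sigma2) * z)
    return pd.DataFrame(
        vals,
        index=pd.Index(names, name="amino_acid"),
        columns=[f"sample_{j + 1}" for j in range(n_samples)],
    )


def export_with_truth(table: pd.DataFrame, path, truth: dict) -> None:
    """Write a generated table as CSV plus a JSON ground-truth sidecar."""
    path = Path(path)
    table.to_csv(path)
    sidecar = path.with_suffix(".truth.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
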