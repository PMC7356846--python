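"""Synthetic data generators and packaged fixtures.

Everything here exists so the full pipeline — curation, embedding,
rendering, splitting, training, evaluation — runs and is testable from an
empty directory, with no downloads:

* the packaged nuclear-receptor assay manifest (35 agonist/antagonist qHTS
  bioassays with their reporter technology, cell line and controls), shipped
  as a checksummed CSV;
* a toy compound library of two geometrically distinguishable structural
  classes — actives carry a bromine atom, whose distinctive dark-red CPK
  color guarantees a desk-scale-learnable image signal — with PubChem-style
  activity scores;
* noisy four-parameter-logistic dose-response series with known truth;
* per-image prediction tables with class-conditional Beta-distributed
  probabilities whose generating-process AUC is computable independently.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .chem_prep import CompoundRecord, curate_record
from .qhts import DoseResponseSeries, hill4

ASSAY_MANIFEST_SHA256 = \
    "0c36612977b88b856c4a8cc5bb3d79a92f514430cead17b12b2712827d549125"

ASSAY_TECHNOLOGIES = frozenset({
    "luciferase", "beta-lactamase", "cAMP assay", "intracellular calcium assay"})


@dataclass(frozen=True)
class AssayManifestEntry:
    pubchem_aid: int
    model_name: str
    receptor: str
    activity: str  # agonist | antagonist
    assay_technology: str
    cell_line: str
    positive_control: Optional[str]  # None where not analyzed
    co_treatment: Optional[str] = None  # reference compound added to wells


class FixtureChecksumError(RuntimeError):
    pass


def load_assay_manifest() -> list[AssayManifestEntry]:
    """The packaged 35-assay manifest, verified against its checksum."""
    path = resources.files("molsnap.data").joinpath("assay_manifest.csv")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != ASSAY_MANIFEST_SHA256:
        raise FixtureChecksumError(
            f"assay manifest checksum mismatch: {digest}")
    df = pd.read_csv(path, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        tech = row.assay_technology
        if tech not in ASSAY_TECHNOLOGIES:
            raise ValueError(f"unknown assay technology {tech!r}")
        entries.append(AssayManifestEntry(
            pubchem_aid=int(row.pubchem_aid),
            model_name=row.model_name,
            receptor=row.receptor,
            activity=row.activity,
            assay_technology=tech,
            cell_line=row.cell_line,
            positive_control=None if row.positive_control == "NA"
            else row.positive_control,
            co_treatment=row.co_treatment or None))
    return entries


# ---------------------------------------------------------------------------
# toy compound library


def _scaffold_series() -> list[str]:
    """Deterministic pool of structurally unique hydrocarbon scaffolds.

    Pure hydrocarbons by design: both classes then share an identical
    element palette except for the active motif, so the only categorical
    image difference between classes is the motif color, not incidental
    heteroatom content.
    """
    scaffolds: list[str] = []
    for i in range(1, 13):
        scaffolds.append("C" * i)                 # linear alkanes
    for i in range(1, 11):
        scaffolds.append("CC(C)" + "C" * i)       # 2-methyl branches
    for i in range(1, 9):
        scaffolds.append("CC(C)(C)" + "C" * i)    # 2,2-dimethyl branches
    for i in range(0, 9):
        scaffolds.append("C1CCCCC1" + "C" * i)    # cyclohexyl chains
    return scaffolds


@dataclass(frozen=True)
class ToyLibrarySpec:
    n_per_class: int = 20
    active_motif: str = "Br"  # structural feature carried by actives
    scaffold_pool: tuple[str, ...] = tuple(_scaffold_series())
    label_noise: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_per_class > len(self.scaffold_pool):
            raise ValueError("not enough scaffolds for n_per_class")


def make_toy_library(spec: ToyLibrarySpec = ToyLibrarySpec()) -> list[CompoundRecord]:
    """Two structural classes on shared scaffolds: actives = motif + scaffold.

    Active scores are drawn uniformly from 40-100, inactive from 0-39;
    a label_noise fraction of records has its score resampled from the other
    range (structure keeps the motif, so labels become wrong on purpose).
    Records come back curated (canonicalized and labeled).
    """
    rng = np.random.default_rng(spec.seed)
    pool = list(spec.scaffold_pool)
    order = rng.permutation(len(pool))
    chosen = [pool[i] for i in order[:spec.n_per_class]]

    records: list[CompoundRecord] = []
    for k, scaffold in enumerate(chosen):
        active_smiles = spec.active_motif + scaffold
        records.append(CompoundRecord(
            compound_id=f"ACT{k:04d}", smiles=active_smiles,
            activity_score=int(rng.integers(40, 101))))
        records.append(CompoundRecord(
            compound_id=f"INA{k:04d}", smiles=scaffold,
            activity_score=int(rng.integers(0, 40))))

    n_flip = int(round(spec.label_noise * len(records)))
    if n_flip:
        flip_idx = rng.choice(len(records), size=n_flip, replace=False)
        for i in flip_idx:
            rec = records[i]
            if rec.activity_score >= 40:
                rec.activity_score = int(rng.integers(0, 40))
            else:
                rec.activity_score = int(rng.integers(40, 101))

    curated = [curate_record(r) for r in records]
    canon = [r.canonical_smiles for r in curated if r.kept]
    if len(set(canon)) != len(canon):
        raise RuntimeError("scaffold pool produced duplicate structures")
    return curated


def write_library_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame([{"compound_id": r.compound_id, "smiles": r.smiles,
                   "activity_score": r.activity_score}
                  for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dose-response series


def make_dose_response(bottom: float = 0.0, top: float = 100.0,
                       ic50: float = 1e-6, hill_slope: float = 1.0,
                       n_points: int = 8, sigma: float = 0.0,
                       seed: int = 1, decades: float = 3.0,
                       mode: str = "agonist") -> DoseResponseSeries:
    """Log-spaced concentrations spanning +-decades around IC50, 4PL
    responses plus Gaussian noise of sd sigma (% Activity units)."""
    if n_points < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(seed)
    conc = np.logspace(np.log10(ic50) - decades, np.log10(ic50) + decades,
                       n_points)
    resp = hill4(conc, bottom, top, ic50, hill_slope)
    if sigma > 0:
        resp = resp + rng.normal(0.0, sigma, size=n_points)
    return DoseResponseSeries(concentrations=conc, responses=resp, mode=mode)


# ---------------------------------------------------------------------------
# prediction tables


def _beta_params(mean: float, concentration: float = 10.0) -> tuple[float, float]:
    mean = float(np.clip(mean, 0.02, 0.98))
    return mean * concentration, (1.0 - mean) * concentration


def beta_pair_auc(separation: float, concentration: float = 10.0) -> float:
    """Generating-process AUC: P(p_active > p_inactive) for the two
    class-conditional Beta laws, by numerical integration (independent of
    any empirical ROC code)."""
    a1, b1 = _beta_params(0.5 + separation / 2.0, concentration)
    a0, b0 = _beta_params(0.5 - separation / 2.0, concentration)
    f_act = stats.beta(a1, b1)
    f_ina = stats.beta(a0, b0)
    val, _ = integrate.quad(lambda x: f_act.pdf(x) * f_ina.cdf(x), 0.0, 1.0,
                            limit=200)
    return float(val)


def make_prediction_table(n_molecules: int = 40, n_poses: int = 27,
                          separation: float = 0.4, seed: int = 1,
                          concentration: float = 10.0) -> pd.DataFrame:
    """Per-image probabilities from class-conditional Beta distributions.

    Half the molecules are active (mean 0.5 + separation/2), half inactive
    (mean 0.5 - separation/2); each molecule contributes n_poses rows.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    n_active = n_molecules // 2
    for m in range(n_molecules):
        is_active = m < n_active
        mean = 0.5 + (separation / 2.0 if is_active else -separation / 2.0)
        a, b = _beta_params(mean, concentration)
        probs = rng.beta(a, b, size=n_poses)
        for k, p in enumerate(probs):
            rows.append({
                "compound_id": f"M{m:04d}",
                "theta_x": float(k), "theta_y": 0.0, "theta_z": 0.0,
                "label": "active" if is_active else "inactive",
                "probability_active": float(p)})
    return pd.DataFrame(rows)
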