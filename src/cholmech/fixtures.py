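"""Synthetic compound tables and transporter IC50 training sets.

Everything downstream — I/O, featurization, QSAR training, PBTK/QIVIVE,
rule classification, metrics — is testable offline against data whose
ground truth is known by construction:

* compounds are drawn from a built-in library of real drug-like SMILES;
* FUB, CLint and the maximum therapeutic dose are sampled log-uniformly
  within plausible ranges;
* each transporter gets a planted pIC50 surface — a linear function of the
  standardized physicochemical descriptor block — plus Gaussian noise for
  training tables;
* the binary cholestasis label is assigned by actually running the
  generative rule (noise-free planted IC50s, QIVIVE at the default
  physiology, OR rule at K = 1), so a pipeline holding the exact oracle
  models must reproduce the labels.

``signal_strength`` is the fraction of pIC50 variance carried by the
planted signal: the signal standard deviation is
``noise_sd * sqrt(s / (1 - s))`` (and 1.0 pIC50 units when ``noise_sd`` is
zero or ``s`` = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import descriptors, pbtk
from .compound_io import CompoundRecord, CompoundTable
from .data._smiles_library import DRUG_SMILES
from .qsar_panel import TRANSPORTERS, TransporterPanel

#: baseline pIC50 of the planted surfaces (IC50 ~ 10 µM at pIC50 5)
BASE_PIC50 = 5.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    n_compounds: int = 426  # mirrors the reference-set size
    seed: int = 0
    fub_range: Tuple[float, float] = (0.01, 1.0)
    clint_range: Tuple[float, float] = (1.0, 100.0)  # µL/min/1e6 cells
    dose_range: Tuple[float, float] = (5.0, 1000.0)  # mg/day
    signal_strength: float = 0.8
    noise_sd: float = 0.5  # pIC50 units

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        for name in ("fub_range", "clint_range", "dose_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.fub_range[1] > 1.0:
            raise ValueError("fub_range must stay within (0, 1]")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def signal_sd(self) -> float:
        s = self.signal_strength
        if s == 0.0:
            return 0.0
        if self.noise_sd == 0.0 or s >= 1.0:
            return 1.0
        return float(self.noise_sd * np.sqrt(s / (1.0 - s)))


@lru_cache(maxsize=1)
def _library_physchem() -> np.ndarray:
    """Physchem block for every library SMILES (cached)."""
    return np.vstack([descriptors.physchem_block(s) for s in DRUG_SMILES])


@lru_cache(maxsize=1)
def _library_stats() -> Tuple[np.ndarray, np.ndarray]:
    phys = _library_physchem()
    mu = phys.mean(axis=0)
    sd = phys.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


class PlantedIC50Model:
    """Noise-free planted pIC50 surface, usable as a fitted panel estimator.

    Predicts from the trailing physchem columns of the full feature matrix,
    so it plugs directly into :class:`TransporterPanel`.
    """

    def __init__(self, weights: np.ndarray, base: float, signal_sd: float):
        mu, sd = _library_stats()
        self._mu, self._sd = mu, sd
        self.weights = np.asarray(weights, dtype=float)
        self.base = float(base)
        # standardize the raw projection over the library so the planted
        # signal has exactly signal_sd spread across library chemistry
        raw = ((_library_physchem() - mu) / sd) @ self.weights
        self._raw_mu = float(raw.mean())
        self._raw_sd = float(raw.std()) or 1.0
        self.signal_sd = float(signal_sd)

    def pic50_from_physchem(self, phys: np.ndarray) -> np.ndarray:
        phys = np.atleast_2d(np.asarray(phys, dtype=float))
        raw = ((phys - self._mu) / self._sd) @ self.weights
        return self.base + self.signal_sd * (raw - self._raw_mu) / self._raw_sd

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.pic50_from_physchem(X[:, -descriptors.N_PHYSCHEM :])


def planted_models(spec: FixtureSpec) -> Dict[str, PlantedIC50Model]:
    """The per-transporter planted surfaces implied by ``spec.seed``."""
    models = {}
    for i, transporter in enumerate(TRANSPORTERS):
        rng = np.random.default_rng([spec.seed % (2**31), 7919 + i])
        w = rng.normal(size=descriptors.N_PHYSCHEM)
        models[transporter] = PlantedIC50Model(w, BASE_PIC50, spec.signal_sd)
    return models


def make_oracle_panel(spec: FixtureSpec) -> TransporterPanel:
    """A panel whose 'fitted estimators' are the exact planted surfaces."""
    panel = TransporterPanel()
    for transporter, model in planted_models(spec).items():
        panel.estimators[transporter] = model
        panel.seeds[transporter] = spec.seed
    return panel


def _sample_loguniform(rng, lo, hi, n):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_compound_table(spec: FixtureSpec) -> CompoundTable:
    """Draw a validated synthetic compound table with planted labels.

    Labels come from the generative rule itself: a compound is cholestatic
    when its therapeutic dose (mg/kg/day) strictly exceeds the QIVIVE dose
    of at least one transporter's planted (noise-free) IC50 at K = 1.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 104729])
    idx = rng.integers(0, len(DRUG_SMILES), size=spec.n_compounds)
    fub = _sample_loguniform(rng, *spec.fub_range, spec.n_compounds)
    clint = _sample_loguniform(rng, *spec.clint_range, spec.n_compounds)
    dose_max = _sample_loguniform(rng, *spec.dose_range, spec.n_compounds)
    models = planted_models(spec)

    records = []
    for j in range(spec.n_compounds):
        smiles = DRUG_SMILES[int(idx[j])]
        phys = descriptors.physchem_block(smiles)
        mw = phys[0]
        params = pbtk.build_parameters(fub=float(fub[j]), clint=float(clint[j]))
        css_unit = pbtk.css_analytic(params, 1.0)
        td_per_kg = dose_max[j] / params.body_weight
        positive = False
        for model in models.values():
            pic50 = float(model.pic50_from_physchem(phys)[0])
            ic50_uM = 10.0 ** (6.0 - pic50)
            in_vivo = (ic50_uM * mw / 1000.0) / css_unit  # mg/kg/day, K = 1
            if td_per_kg > in_vivo:
                positive = True
                break
        records.append(
            CompoundRecord(
                name=f"FIX-{j:04d}",
                chembl_id=f"SYN{j:06d}",
                smiles=smiles,
                dose_max=float(dose_max[j]),
                activity=int(positive),
                fub=float(fub[j]),
                clint=float(clint[j]),
            )
        )
    return CompoundTable(records=records, source="inline")


def generate_ic50_training_set(
    spec: FixtureSpec, transporter: str, n: Optional[int] = None
) -> pd.DataFrame:
    """Synthetic (SMILES, ic50_uM) training table for one transporter.

    pIC50 = planted surface + N(0, noise_sd); back-transformed to µM.
    """
    if transporter not in TRANSPORTERS:
        raise ValueError(f"unknown transporter {transporter!r}")
    n = n or spec.n_compounds
    t_index = TRANSPORTERS.index(transporter)
    rng = np.random.default_rng([spec.seed % (2**31), 15485863 + t_index])
    idx = rng.integers(0, len(DRUG_SMILES), size=n)
    smiles = [DRUG_SMILES[int(i)] for i in idx]
    model = planted_models(spec)[transporter]
    phys = np.vstack([descriptors.physchem_block(s) for s in smiles])
    pic50 = model.pic50_from_physchem(phys) + rng.normal(0.0, spec.noise_sd, size=n)
    return pd.DataFrame({"SMILES": smiles, "ic50_uM": 10.0 ** (6.0 - pic50)})
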