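"""Seedable synthetic benchmarks with known ground truth.

The regression generator emulates the geometry that makes real bioactivity
datasets modelable: compounds live along a low-dimensional "chemical
series" axis (a latent coordinate), every descriptor or fingerprint bit
is a noisy view of that axis, and activity varies smoothly along it — so
whole-feature-space similarity tracks activity (the similarity principle
behind the modelability index).  Concretely:

* each row draws a latent position u in [0, 1];
* every feature is a clipped affine projection of u plus feature noise —
  the ``n_informative`` designated columns with very low noise, the rest
  with high noise;
* half the distractor columns (by default) are binarized at 0.5 with
  per-column offsets, producing fingerprint-like bits whose Hamming
  distance grows with latent distance (a thermometer code);
* the response is a function of the *realized* informative columns only
  (linear, or with an interaction and a quadratic term), min-max squashed
  onto [0, 1] like scaled bioactivities, plus Gaussian noise.

Because only the informative columns enter the response and they are the
least noisy views of the latent axis, feature-ranking methods should
recover them, while kNN in the full feature space still predicts activity
well (high MODI).  The activity-cliff generator breaks the similarity
principle on purpose: near-duplicate feature pairs carry activities near
0 and near 1, which depresses MODI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .featurize import FeatureMatrix
from .transform import ScaledActivities

# feature-noise scales of the latent-projection views (fractions of the
# unit feature range); informative columns are near-deterministic so the
# response is attributable to them alone
_INFORMATIVE_NOISE = 0.01
_DISTRACTOR_NOISE = 0.25
_BINARY_NOISE = 0.05
_LATENT_GAIN = 0.8
_BINARY_OFFSET = 0.35
_CLIFF_PERTURBATION = 1e-3


@dataclass(frozen=True)
class SyntheticSpec:
    """Dataset size, signal sparsity and noise for the generators."""

    n: int = 300
    p: int = 200
    n_informative: int = 10
    noise_sd: float = 0.05
    cliff_fraction: float = 0.0
    seed: int = 0
    response_form: str = "nonlinear"
    binarize_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p <= 0 or self.n_informative <= 0:
            raise ConfigurationError("n, p and n_informative must be positive")
        if self.n_informative > self.p:
            raise ConfigurationError("n_informative cannot exceed p")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.cliff_fraction <= 1:
            raise ConfigurationError("cliff_fraction must be in [0, 1]")
        if self.response_form not in ("linear", "nonlinear"):
            raise ConfigurationError("response_form must be 'linear' or 'nonlinear'")
        if not 0 <= self.binarize_fraction <= 1:
            raise ConfigurationError("binarize_fraction must be in [0, 1]")


def _feature_model(spec: SyntheticSpec, rng: np.random.Generator):
    """Draw the per-column projection signs, noises, offsets and response
    coefficients shared by both generators."""
    p, k = spec.p, spec.n_informative
    signs = np.where(rng.random(p) < 0.5, -1.0, 1.0)
    informative = np.sort(rng.choice(p, size=k, replace=False))
    rest = np.setdiff1d(np.arange(p), informative)
    n_bin = min(int(round(spec.binarize_fraction * p)), rest.size)
    binary = np.sort(rng.choice(rest, size=n_bin, replace=False))
    sigma = np.full(p, _DISTRACTOR_NOISE)
    sigma[informative] = _INFORMATIVE_NOISE
    sigma[binary] = _BINARY_NOISE
    offsets = np.zeros(p)
    offsets[binary] = rng.uniform(-_BINARY_OFFSET, _BINARY_OFFSET, size=n_bin)
    # response coefficients aligned with each informative column's
    # projection sign: the informative contributions add coherently along
    # the latent axis instead of cancelling (a cancelled response would be
    # dominated by feature noise after the [0,1] squash)
    beta = rng.uniform(0.5, 1.5, size=k) * signs[informative]
    return signs, informative, binary, sigma, offsets, beta


def _features_from_latent(u, signs, sigma, offsets, binary, rng) -> np.ndarray:
    raw = 0.5 + offsets + _LATENT_GAIN * np.outer(u - 0.5, signs)
    X = np.clip(raw + rng.normal(size=raw.shape) * sigma, 0.0, 1.0)
    X[:, binary] = (X[:, binary] > 0.5).astype(float)
    return X


def _response(V: np.ndarray, beta: np.ndarray, form: str) -> np.ndarray:
    k = V.shape[1]
    y0 = V @ beta
    if form == "nonlinear":
        y0 = y0 + V[:, 0] * V[:, 1 % k] + (V[:, 2 % k] - 0.5) ** 2
    lo, hi = y0.min(), y0.max()
    if hi > lo:
        y0 = (y0 - lo) / (hi - lo)
    return y0


def _feature_names(p: int) -> list[str]:
    return [f"feat{j:04d}" for j in range(p)]


def _package(X, y, spec, informative) -> tuple[FeatureMatrix, ScaledActivities, list[str]]:
    names = _feature_names(spec.p)
    ids = [f"cmp{i + 1:04d}" for i in range(X.shape[0])]
    df = pd.DataFrame(X, index=ids, columns=names)
    kind = pd.Series("descriptor", index=df.columns)
    # tag the fingerprint-like binary columns for realism
    kind[df.columns[(df.isin([0.0, 1.0])).all(axis=0) & (df.nunique() <= 2)]] = "fingerprint"
    fm = FeatureMatrix(df, kind, {"generator": "synthetic", "seed": spec.seed})
    acts = ScaledActivities(pd.Series(y, index=ids), skip_flag=True)
    return fm, acts, [names[j] for j in informative]


def make_regression_dataset(spec: SyntheticSpec):
    """Generate a smooth, modelable benchmark with a known informative subset.

    Returns ``(features, activities, informative_feature_names)``; with
    ``noise_sd=0`` and the linear form the response is an exact affine
    function of the informative columns, so PVE 1 is achievable.
    """
    if spec.cliff_fraction != 0:
        raise ConfigurationError("use make_activity_cliff_dataset for cliff_fraction > 0")
    rng = np.random.default_rng(spec.seed)
    signs, informative, binary, sigma, offsets, beta = _feature_model(spec, rng)
    u = rng.uniform(size=spec.n)
    X = _features_from_latent(u, signs, sigma, offsets, binary, rng)
    y = _response(X[:, informative], beta, spec.response_form)
    if spec.noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, spec.noise_sd, size=spec.n), 0.0, 1.0)
    return _package(X, y, spec, informative)


def make_activity_cliff_dataset(spec: SyntheticSpec):
    """Generate a low-modelability dataset riddled with activity cliffs.

    ``cliff_fraction`` of the rows come in near-duplicate feature pairs
    (perturbation far below typical inter-point distance) whose two
    members carry activities near 0 and near 1; the remaining rows follow
    the smooth regression model.  Returns ``(features, activities)``.
    """
    if spec.cliff_fraction == 0:
        fm, acts, _ = make_regression_dataset(spec)
        return fm, acts
    rng = np.random.default_rng(spec.seed)
    signs, informative, binary, sigma, offsets, beta = _feature_model(spec, rng)
    n_pairs = int(spec.cliff_fraction * spec.n) // 2
    n_smooth = spec.n - 2 * n_pairs

    if n_smooth:
        u_smooth = rng.uniform(size=n_smooth)
        X_smooth = _features_from_latent(u_smooth, signs, sigma, offsets, binary, rng)
        y_smooth = _response(X_smooth[:, informative], beta, spec.response_form)
        if spec.noise_sd > 0:
            y_smooth = np.clip(y_smooth + rng.normal(0, spec.noise_sd, n_smooth), 0, 1)

    u_base = rng.uniform(size=n_pairs)
    base = _features_from_latent(u_base, signs, sigma, offsets, binary, rng)
    jitter = rng.normal(0.0, _CLIFF_PERTURBATION, size=base.shape)
    twin = np.clip(base + jitter, 0.0, 1.0)
    twin[:, binary] = base[:, binary]  # bits identical within a pair
    y_low = rng.uniform(0.0, 0.05, size=n_pairs)
    y_high = rng.uniform(0.95, 1.0, size=n_pairs)

    X = np.vstack([X_smooth, base, twin]) if n_smooth else np.vstack([base, twin])
    y = np.concatenate([y_smooth, y_low, y_high]) if n_smooth else np.concatenate([y_low, y_high])
    fm, acts, _ = _package(X, y, spec, informative)
    return fm, acts


def make_smiles_fixture() -> list[tuple[str, str, str, float | None, int | None]]:
    """An embedded compound list exercising every curation branch.

    Hand-curated drug-like SMILES with plausible nM activities; includes
    deliberate same-structure duplicates (different years), a salt form
    duplicating its parent, one invalid SMILES and one missing activity.
    Returns ``(id, smiles, activity_type, activity_value_nM, year)`` rows.
    """
    return list(_SMILES_FIXTURE)


# Planted irregularities (ids):
#   F031/F032  same structure, years 2012/2019 -> 2019 kept, 1 dropped
#   F033/F034  aspirin + its sodium salt       -> same parent, 1 dropped
#   F035/F036/F037 same structure, tied year   -> median-activity kept, 2 dropped
#   F038       invalid SMILES                  -> rejected
#   F039       missing activity                -> dropped
#   F040       IC50 record                     -> dropped on a Ki query
_SMILES_FIXTURE: tuple = (
    ("F001", "CC(=O)Nc1ccc(O)cc1", "Ki", 5200.0, 2015),
    ("F002", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Ki", 880.0, 2016),
    ("F003", "CN1CCC[C@H]1c1cccnc1", "Ki", 45.0, 2011),
    ("F004", "Clc1ccccc1-c1nc2ccccc2[nH]1", "Ki", 230.0, 2018),
    ("F005", "COc1ccc2cc(ccc2c1)C(C)C(=O)O", "Ki", 1500.0, 2014),
    ("F006", "CN(C)CCCN1c2ccccc2Sc2ccccc21", "Ki", 12.0, 2013),
    ("F007", "NC(=O)c1ccc(cc1)S(=O)(=O)N", "Ki", 7600.0, 2017),
    ("F008", "O=C(O)c1ccccc1O", "Ki", 9100.0, 2010),
    ("F009", "CCN(CC)CCNC(=O)c1ccc(N)cc1", "Ki", 310.0, 2019),
    ("F010", "CC(N)Cc1ccccc1", "Ki", 2100.0, 2012),
    ("F011", "Oc1ccc(CCN2CCCCC2)cc1", "Ki", 66.0, 2020),
    ("F012", "CC(=O)Oc1ccccc1C(=O)OC", "Ki", 4900.0, 2015),
    ("F013", "c1ccc(cc1)C(c1ccccc1)N1CCNCC1", "Ki", 150.0, 2016),
    ("F014", "CN1CCN(CC1)c1ccccc1", "Ki", 980.0, 2011),
    ("F015", "COc1cc2c(cc1OC)CCN(C)C2", "Ki", 420.0, 2018),
    ("F016", "Fc1ccc(cc1)C(=O)CCCN1CCC(O)CC1", "Ki", 8.5, 2014),
    ("F017", "CCOC(=O)C1(CCN(C)CC1)c1ccccc1", "Ki", 540.0, 2013),
    ("F018", "NC1=NC(=O)N(C=C1)[C@H]1CCCO1", "Ki", 6700.0, 2017),
    ("F019", "CN(C)CCOC(c1ccccc1)c1ccccc1", "Ki", 95.0, 2019),
    ("F020", "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1", "Ki", 3.2, 2012),
    ("F021", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O", "Ki", 28.0, 2020),
    ("F022", "COc1ccc(CCNCC(O)c2ccc(O)c(O)c2)cc1", "Ki", 760.0, 2015),
    ("F023", "O=C1N(CCCCN2CCN(CC2)c2cccc(Cl)c2)C(=O)c2ccccc21", "Ki", 1.8, 2016),
    ("F024", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "Ki", 9800.0, 2010),
    ("F025", "NS(=O)(=O)c1cc2c(cc1Cl)NC(=O)NS2(=O)=O", "Ki", 3400.0, 2011),
    ("F026", "CC(CS)C(=O)N1CCCC1C(=O)O", "Ki", 1200.0, 2018),
    ("F027", "c1ccc2c(c1)oc1ccccc12", "Ki", 8900.0, 2014),
    ("F028", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", "Ki", 380.0, 2013),
    ("F029", "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1", "Ki", 19.0, 2017),
    ("F030", "O=C(CCCN1CCC(CC1)n1c2ccccc2nc1O)c1ccc(F)cc1", "Ki", 2.4, 2019),
    # duplicate pair, distinct years -> most recent kept
    ("F031", "CN1CCCC1c1cccnc1", "Ki", 50.0, 2012),
    ("F032", "CN1CCCC1c1cccnc1", "Ki", 40.0, 2019),
    # hydrochloride salt duplicating its desalted parent (same canonical parent)
    ("F033", "CN1CCc2ccccc2C1", "Ki", 640.0, 2016),
    ("F034", "CN1CCc2ccccc2C1.Cl", "Ki", 700.0, 2016),
    # triplicate with tied years -> median activity representative kept
    ("F035", "NCCc1ccc(O)c(O)c1", "Ki", 100.0, 2015),
    ("F036", "NCCc1ccc(O)c(O)c1", "Ki", 200.0, 2015),
    ("F037", "NCCc1ccc(O)c(O)c1", "Ki", 400.0, 2015),
    # invalid structure
    ("F038", "notasmiles", "Ki", 55.0, 2018),
    # missing activity value
    ("F039", "Cc1ccccc1Nc1ncccn1", "Ki", None, 2017),
    # wrong activity type for a Ki query
    ("F040", "CCOc1ccc2nc(S(N)(=O)=O)sc2c1", "IC50", 140.0, 2015),
)
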