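"""Synthetic seed-orchard progeny simulator.

Generates an open-pollinated progeny population from a set of clonal orchard
parents, plants the offspring across climatically graded sites, and records
two genetically correlated traits with known (true) additive genetics, so
that every downstream stage of the pipeline can be tested by parameter
recovery without any external data.

Draw order with a fixed seed is: pedigree (dams, contamination flags,
sires) -> climate -> breeding values (parents, external founders, Mendelian
deviations) -> site ages -> residuals.  A single ``numpy`` Generator stream
drives everything, so output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, validate_pedigree, write_pedigree_csv


class ConfigError(ValueError):
    pass


def _as_matrix(x) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.shape != (2, 2):
        raise ConfigError("covariance matrices must be 2x2")
    return m


def _check_psd(m: np.ndarray, name: str) -> None:
    if not np.allclose(m, m.T):
        raise ConfigError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ConfigError(f"{name} must be positive semi-definite")


# Default genetic/residual covariances reproduce h2(mai)=0.27, h2(density)=0.30
# and an additive correlation of 0.09 on a phenotypic scale of var 100 (mai,
# cm/year) and var 1 (density, dimensionless).
_DEFAULT_G0 = ((27.0, 0.09 * np.sqrt(27.0 * 0.30)), (0.09 * np.sqrt(27.0 * 0.30), 0.30))
_DEFAULT_R0 = ((73.0, 0.10 * np.sqrt(73.0 * 0.70)), (0.10 * np.sqrt(73.0 * 0.70), 0.70))


@dataclass
class SimConfig:
    """Configuration of the synthetic orchard.

    The true population response curve is the quadratic ``beta0 + beta1*c +
    beta2*c**2`` in the winter-temperature gradient variable ``mtcm``; the
    defaults place its vertex at (-2.2 degC, 65 cm/year).  The mean annual
    increment trait is recorded as ``height = mai * age``.
    """

    n_parents: int = 53
    n_sites: int = 21
    offspring_per_site: int = 62
    contamination_rate: float = 0.084
    g0: tuple = _DEFAULT_G0
    r0: tuple = _DEFAULT_R0
    beta: tuple = (40.8, -22.0, -5.0)
    mtcm_range: tuple = (-4.0, 0.0)
    age_range: tuple = (25, 37)
    climate_noise: float = 0.2  # noise sd relative to each collinear variable's sd
    n_decoys: int = 5
    density_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ConfigError("contamination_rate must be in [0, 1]")
        if self.n_sites < 3:
            raise ConfigError("need at least 3 sites for an identifiable quadratic")
        if self.n_parents < 2:
            raise ConfigError("need at least 2 orchard parents")
        _check_psd(self.G0, "g0")
        _check_psd(self.R0, "r0")

    @property
    def G0(self) -> np.ndarray:
        return _as_matrix(self.g0)

    @property
    def R0(self) -> np.ndarray:
        return _as_matrix(self.r0)

    @property
    def n_offspring(self) -> int:
        return self.n_sites * self.offspring_per_site

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["g0"] = self.G0.tolist()
        d["r0"] = self.R0.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticDataset:
    """A simulated dataset plus the generating truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame  # individual, site, age, height, density
    climate: pd.DataFrame  # site + one column per climatic variable
    true_breeding_values: pd.DataFrame  # individual, bv_mai, bv_density
    true_site_effects: pd.DataFrame  # site, effect (cm/year, mai scale)
    config: SimConfig

    def write(self, outdir) -> dict:
        """Write the three CSV tables plus a JSON truth sidecar; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": outdir / "ped.csv",
            "phenotypes": outdir / "phen.csv",
            "climate": outdir / "climate.csv",
            "true_breeding_values": outdir / "true_bv.csv",
            "truth": outdir / "truth.json",
        }
        write_pedigree_csv(self.pedigree, paths["pedigree"])
        self.phenotypes.to_csv(paths["phenotypes"], index=False)
        self.climate.to_csv(paths["climate"], index=False)
        self.true_breeding_values.to_csv(paths["true_breeding_values"], index=False)
        truth = {
            "config": self.config.to_dict(),
            "site_effects": {
                str(r["site"]): float(r["effect"])
                for _, r in self.true_site_effects.iterrows()
            },
        }
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


def _parent_ids(n: int) -> list:
    return [f"P{i + 1:02d}" for i in range(n)]


def _site_ids(n: int) -> list:
    return [f"S{i + 1:02d}" for i in range(n)]


def simulate_pedigree(
    cfg: SimConfig, rng: np.random.Generator | None = None, n_offspring: int | None = None
) -> Pedigree:
    """Open-pollination mating among orchard parents with pollen contamination.

    Each offspring draws its dam uniformly from the orchard parents.  With
    probability ``contamination_rate`` the sire is an external (out-of-orchard)
    tree, recorded as unknown and flagged; otherwise it is a uniform draw from
    the other parents (no selfing).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_off = cfg.n_offspring if n_offspring is None else n_offspring
    parents = _parent_ids(cfg.n_parents)

    dams = rng.integers(0, cfg.n_parents, size=n_off)
    external = rng.random(n_off) < cfg.contamination_rate
    sires = rng.integers(0, cfg.n_parents - 1, size=n_off)
    sires = sires + (sires >= dams)  # skip the dam: no selfing

    records = [(p, None, None) for p in parents]
    flagged = []
    for k in range(n_off):
        oid = f"O{k + 1:05d}"
        if external[k]:
            records.append((oid, None, parents[dams[k]]))
            flagged.append(oid)
        else:
            records.append((oid, parents[sires[k]], parents[dams[k]]))
    return validate_pedigree(records, flagged)


def simulate_climate(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site climate table with a collinear winter-temperature block.

    ``mtcm`` is spread evenly over ``mtcm_range``; six companion variables
    (January/December minima, December mean, January/December maxima, and
    altitude) are affine transforms of mtcm plus noise scaled so that
    within-block pairwise |r| stays above 0.85; ``n_decoys`` precipitation-like
    variables are pure noise.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.mtcm_range
    mtcm = np.linspace(lo, hi, cfg.n_sites)
    sd = float(np.std(mtcm))

    # (name, intercept, slope); altitude decreases with winter temperature
    transforms = [
        ("tmin_jan", -2.0, 1.0),
        ("tmin_dec", -1.5, 1.0),
        ("tmean_dec", 0.5, 1.0),
        ("tmax_jan", 3.0, 1.0),
        ("tmax_dec", 2.5, 1.0),
        ("altitude", 760.0 + 120.0 * lo, -120.0),
    ]
    data = {"site": _site_ids(cfg.n_sites), "mtcm": mtcm}
    for name, a, b in transforms:
        noise = rng.normal(0.0, cfg.climate_noise * abs(b) * sd, cfg.n_sites)
        data[name] = a + b * mtcm + noise
    for k in range(cfg.n_decoys):
        data[f"prec_{k + 1:02d}"] = rng.normal(800.0, 100.0, cfg.n_sites)
    return pd.DataFrame(data)


def true_site_effect(cfg: SimConfig, mtcm: np.ndarray) -> np.ndarray:
    b0, b1, b2 = cfg.beta
    c = np.asarray(mtcm, dtype=float)
    return b0 + b1 * c + b2 * c * c


def simulate_phenotypes(
    ped: Pedigree,
    climate: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Drop breeding values down the pedigree and record phenotypes.

    Founder breeding values are bivariate normal ``N(0, G0)``; an offspring's
    value is the parental average plus a Mendelian deviation with covariance
    ``G0/2``.  Externally-sired offspring receive an explicit external-founder
    draw for the missing sire, which marginally yields the 3/4*G0 Mendelian
    covariance of the one-unknown-parent case.  The site effect on the MAI
    scale lies exactly on the configured quadratic in mtcm.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    G0, R0 = cfg.G0, cfg.R0
    L_g = np.linalg.cholesky(G0 + 1e-12 * np.eye(2))
    L_m = np.linalg.cholesky(0.5 * G0 + 1e-12 * np.eye(2))
    L_r = np.linalg.cholesky(R0 + 1e-12 * np.eye(2))

    ids = ped.ids
    n = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    founders = [i for i, r in enumerate(ped.records) if r[1] is None and r[2] is None]
    n_ext = len(ped.external_sired)

    bv = np.zeros((n, 2))
    bv[founders] = rng.standard_normal((len(founders), 2)) @ L_g.T
    ext_bv = rng.standard_normal((n_ext, 2)) @ L_g.T
    ext_iter = iter(ext_bv)
    mendelian = rng.standard_normal((n, 2)) @ L_m.T
    for i, (ind, sire, dam) in enumerate(ped.records):
        if sire is None and dam is None:
            continue
        sire_bv = next(ext_iter) if ind in ped.external_sired else (
            bv[idx[sire]] if sire is not None else np.zeros(2)
        )
        dam_bv = bv[idx[dam]] if dam is not None else np.zeros(2)
        bv[i] = 0.5 * (sire_bv + dam_bv) + mendelian[i]

    offspring = list(ped.offspring_ids)
    n_off = len(offspring)
    sites = climate["site"].tolist()
    if len(sites) != cfg.n_sites:
        raise ConfigError("climate table does not match config n_sites")
    site_of = [sites[k % len(sites)] for k in range(n_off)]  # round-robin planting

    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=len(sites))
    age_of_site = dict(zip(sites, ages))
    site_eff = true_site_effect(cfg, climate["mtcm"].to_numpy())
    eff_of_site = dict(zip(sites, site_eff))

    resid = rng.standard_normal((n_off, 2)) @ L_r.T
    off_idx = np.array([idx[o] for o in offspring])
    mai = np.array([eff_of_site[s] for s in site_of]) + bv[off_idx, 0] + resid[:, 0]
    density = cfg.density_mean + bv[off_idx, 1] + resid[:, 1]
    age = np.array([age_of_site[s] for s in site_of])

    phen = pd.DataFrame(
        {
            "individual": offspring,
            "site": site_of,
            "age": age,
            "height": mai * age,
            "density": density,
        }
    )
    true_bv = pd.DataFrame(
        {"individual": list(ids), "bv_mai": bv[:, 0], "bv_density": bv[:, 1]}
    )
    true_eff = pd.DataFrame({"site": sites, "effect": site_eff})
    return SyntheticDataset(ped, phen, climate, true_bv, true_eff, cfg)


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SyntheticDataset:
    """Full simulation in the documented draw order: pedigree, climate, phenotypes."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ped = simulate_pedigree(cfg, rng)
    climate = simulate_climate(cfg, rng)
    return simulate_phenotypes(ped, climate, cfg, rng)
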