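"""CSV/YAML readers and writers and the simulate -> fit -> compare -> cost
pipeline.

File conventions: sites, transects, sessions, years, observers and
individuals are 1-based in files and 0-based in memory.  Detection data
travel as long-form CSV with unsurveyed sessions omitted; banding data as
one row per individual-year from first capture onward.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cjs import BandingData
from .effort import (
    BandCostSpec,
    JointCostSpec,
    PointCostSpec,
    cost_banding,
    cost_detection,
    cost_joint,
    plot_precision,
    precision_report,
    relative_bci_difference,
)
from .inference import McmcConfig, PriorSpec, run_mcmc, summarize
from .occupancy import DetectionData, ModelParams
from .synthetic import (
    CovariateTable,
    StudyDesign,
    default_params,
    generate_covariates,
    generate_design,
    simulate_dataset,
)


class FormatError(ValueError):
    """Malformed input file."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


# ---------------------------------------------------------------------------
# detection data
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = ["site", "transect", "session", "year", "observer", "y"]


def write_detection_csv(path, data: DetectionData, design: StudyDesign) -> None:
    rows = []
    J, Ks, T = data.y.shape
    for j in range(J):
        for k in range(Ks):
            for t in range(T):
                if not data.sampled[j, k, t]:
                    continue
                rows.append((j + 1, design.transect_of_site[j] + 1, k + 1,
                             t + 1, design.observer_assignment[j, k, t] + 1,
                             int(data.y[j, k, t])))
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detection_csv(path, design: StudyDesign | None = None):
    """Read a long-form detection CSV into a dense masked record.

    Rows absent from the file are unsurveyed sessions.  Returns
    ``(DetectionData, StudyDesign)``; when ``design`` is given its
    dimensions are reused (and validated), otherwise a design is
    reconstructed from the file (without nest-box information).
    """
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"detection CSV lacks columns {sorted(missing)}")
    if df.duplicated(subset=["site", "session", "year"]).any():
        raise FormatError("duplicate (site, session, year) rows")
    if not df["y"].isin([0, 1]).all():
        raise FormatError("detection y values must be 0 or 1")
    if design is None:
        J = int(df["site"].max())
        Ks = int(df["session"].max())
        T = int(df["year"].max())
        R = int(df["transect"].max())
        O = int(df["observer"].max())
        transect = np.zeros(J, dtype=np.int64)
        transect[df["site"].to_numpy() - 1] = df["transect"].to_numpy() - 1
        design = StudyDesign(
            n_sites=J, n_transects=R, n_sessions=Ks, n_years=T,
            transect_of_site=transect, nbox_sites=np.array([], dtype=np.int64),
            n_observers=O,
            observer_assignment=np.zeros((J, Ks, T), dtype=np.int64),
            sampled_mask=np.zeros((J, Ks, T), dtype=bool),
        )
    J, Ks, T = design.n_sites, design.n_sessions, design.n_years
    if df["site"].max() > J or df["session"].max() > Ks or df["year"].max() > T:
        raise FormatError("indices exceed the supplied design dimensions")
    y = np.full((J, Ks, T), -1, dtype=np.int8)
    jj = df["site"].to_numpy() - 1
    kk = df["session"].to_numpy() - 1
    tt = df["year"].to_numpy() - 1
    y[jj, kk, tt] = df["y"].to_numpy()
    design.observer_assignment[jj, kk, tt] = df["observer"].to_numpy() - 1
    design.sampled_mask = y >= 0
    return DetectionData(y=y, sampled=y >= 0), design


# ---------------------------------------------------------------------------
# banding data
# ---------------------------------------------------------------------------

BANDING_COLUMNS = ["individual", "site", "sex", "year", "y", "first_capture"]


def write_banding_csv(path, data: BandingData) -> None:
    rows = []
    for i in range(data.n_individuals):
        for t in range(data.f[i], data.n_years):
            rows.append((i + 1, int(data.site[i]) + 1, int(data.sex[i]),
                         t + 1, int(data.y[i, t]), int(data.f[i]) + 1))
    pd.DataFrame(rows, columns=BANDING_COLUMNS).to_csv(path, index=False)


def read_banding_csv(path, n_years: int | None = None) -> BandingData:
    """Read per-individual annual histories; ``first_capture`` may be
    absent, in which case it is inferred from the first detection."""
    df = pd.read_csv(path)
    required = set(BANDING_COLUMNS) - {"first_capture"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"banding CSV lacks columns {sorted(missing)}")
    if not df["y"].isin([0, 1]).all():
        raise FormatError("banding y values must be 0 or 1")
    T = int(n_years or df["year"].max())
    ids = sorted(df["individual"].unique())
    n = len(ids)
    y = np.zeros((n, T), dtype=np.int8)
    site = np.zeros(n, dtype=np.int64)
    sex = np.zeros(n, dtype=np.int8)
    f = np.zeros(n, dtype=np.int64)
    for row_i, ind in enumerate(ids):
        sub = df[df["individual"] == ind]
        y[row_i, sub["year"].to_numpy() - 1] = sub["y"].to_numpy()
        site[row_i] = int(sub["site"].iloc[0]) - 1
        sex[row_i] = int(sub["sex"].iloc[0])
        first_det = int(np.flatnonzero(y[row_i])[0]) if y[row_i].any() else -1
        if first_det < 0:
            raise FormatError(f"individual {ind} has no detection at all")
        if "first_capture" in sub.columns:
            fc = int(sub["first_capture"].iloc[0]) - 1
            if first_det < fc:
                raise FormatError(
                    f"individual {ind}: detection before declared first_capture")
            if y[row_i, fc] != 1:
                raise FormatError(
                    f"individual {ind}: no detection at declared first_capture")
            f[row_i] = fc
        else:
            f[row_i] = first_det
    data = BandingData(y=y, site=site, sex=sex, f=f)
    data.validate()
    return data


def banding_from_histories(histories, sites, sexes) -> BandingData:
    """Build banding data from wide 0/1 encounter-history strings."""
    y = np.array([[int(ch) for ch in h] for h in histories], dtype=np.int8)
    f = np.array([int(np.flatnonzero(row)[0]) for row in y], dtype=np.int64)
    return BandingData(y=y, site=np.asarray(sites, dtype=np.int64),
                       sex=np.asarray(sexes, dtype=np.int8), f=f)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def write_covariates_csv(path, cov: CovariateTable) -> None:
    J, T = cov.tfire.shape
    rows = []
    for j in range(J):
        for t in range(T):
            rows.append((j + 1, int(cov.transect[j]) + 1, t + 1,
                         cov.dnbr[j], int(cov.nbox[j]), int(cov.burned[j]),
                         cov.tfire[j, t], cov.snag[j, t], cov.live[j, t]))
    pd.DataFrame(rows, columns=["site", "transect", "year", "dnbr", "nbox",
                                "burned", "tfire", "snag", "live"]
                 ).to_csv(path, index=False)


def read_covariates_csv(path) -> CovariateTable:
    df = pd.read_csv(path).sort_values(["site", "year"])
    J = int(df["site"].max())
    T = int(df["year"].max())
    site_rows = df[df["year"] == 1].sort_values("site")
    if len(site_rows) != J:
        raise FormatError("covariates CSV must cover every site in year 1")
    def grid(col):
        out = np.zeros((J, T))
        out[df["site"].to_numpy() - 1, df["year"].to_numpy() - 1] = \
            df[col].to_numpy()
        return out
    return CovariateTable(
        dnbr=site_rows["dnbr"].to_numpy(),
        nbox=site_rows["nbox"].to_numpy().astype(np.int8),
        burned=site_rows["burned"].to_numpy().astype(np.int8),
        tfire=grid("tfire"), snag=grid("snag"), live=grid("live"),
        transect=site_rows["transect"].to_numpy().astype(np.int64) - 1,
    )


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "seed": None,
    "design": {"n_sites", "n_transects", "n_sessions", "n_years",
               "nbox_fraction", "n_observers"},
    "covariates": {"burned_fraction", "tfire_mode", "tfire_start"},
    "params": {"a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3", "b4",
               "c0", "c1", "c2", "c3", "c4", "d0", "d1", "e0", "e1",
               "sigma_a", "sigma_d"},
    "marking_rule": None,
    "mcmc": {"n_chains", "n_iter", "burn_in", "thin"},
    "priors": {"slope_var", "intercept_var_b0", "intercept_var_d0",
               "scale_reading", "e0_prior"},
    "costs": {"point", "band", "joint"},
}


@dataclass
class ScenarioConfig:
    """Validated scenario: design + covariate + truth + fit + cost blocks."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    marking_rule: float = 0.3
    mcmc: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    costs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise FormatError(f"unknown scenario keys {sorted(unknown)}")
        for key, allowed in _SCHEMA.items():
            if allowed is None or key not in raw:
                continue
            if not isinstance(raw[key], dict):
                raise FormatError(f"scenario block {key!r} must be a mapping")
            extra = set(raw[key]) - allowed
            if extra:
                raise FormatError(f"unknown keys in {key!r}: {sorted(extra)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def params_to_yaml(path, params: ModelParams) -> None:
    d = {k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
         for k, v in asdict(params).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def params_from_yaml(path) -> ModelParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["a4"] = np.asarray(d["a4"], dtype=float)
    d["d2"] = np.asarray(d["d2"], dtype=float)
    return ModelParams(**d)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _build_world(scenario: ScenarioConfig):
    seed = int(scenario.seed)
    design = generate_design(seed=seed, **scenario.design)
    cov = generate_covariates(design, seed=seed + 1, **scenario.covariates)
    params = default_params(design, seed=seed + 2, **scenario.params)
    return design, cov, params


def simulate_scenario(scenario: ScenarioConfig, out_dir=None):
    """Simulate one dataset from a scenario; optionally write artifacts."""
    design, cov, params = _build_world(scenario)
    ds = simulate_dataset(design, cov, params,
                          marking_rule=scenario.marking_rule,
                          seed=int(scenario.seed))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_detection_csv(out / "detection.csv", ds.detection, design)
        if ds.banding is not None and ds.banding.n_individuals:
            write_banding_csv(out / "banding.csv", ds.banding)
        write_covariates_csv(out / "covariates.csv", cov)
        params_to_yaml(out / "true_params.yaml", params)
    return ds


def run_pipeline(scenario: ScenarioConfig, out_dir) -> dict:
    """simulate -> fit(point) -> fit(band) -> fit(joint) -> compare -> cost.

    Writes posterior summaries, an indicator-support table, a coefficient
    table, the precision report (with violin plot) and an itemized cost
    report; the run log records the seed, a scenario hash and the maximum
    R-hat of every fit.  Any stage failure aborts with a stage-tagged
    error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": int(scenario.seed),
                 "config_hash": scenario.config_hash()}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:                 # noqa: BLE001
            raise PipelineError(f"[{name}] {exc}") from exc

    ds = stage("simulate", lambda: simulate_scenario(scenario, out))
    priors = PriorSpec(**scenario.priors)
    mcmc = McmcConfig(seed=int(scenario.seed), **scenario.mcmc)

    fits = {}
    for model in ("point", "band", "joint"):
        fits[model] = stage(f"fit-{model}", lambda m=model: run_mcmc(
            m, ds.design, ds.covariates, detection=ds.detection,
            banding=ds.banding, priors=priors, config=mcmc))
        summ = summarize(fits[model])
        summ.to_csv(out / f"summary_{model}.csv", index=False)
        max_rhat = float(np.nanmax(summ["rhat"])) if mcmc.n_chains > 1 \
            else float("nan")
        log[f"max_rhat_{model}"] = max_rhat
        if mcmc.n_chains < 2:
            log.setdefault("warnings", []).append(
                f"{model}: single chain, R-hat unavailable")
        log[f"bayesian_pvalue_{model}"] = fits[model].bayesian_pvalue()

    def compare():
        ind = pd.DataFrame({m: fits[m].indicator_means() for m in fits})
        ind.to_csv(out / "indicator_support.csv")
        coef = pd.concat(
            {m: summarize(fits[m]).set_index("parameter") for m in fits},
            axis=1)
        coef.to_csv(out / "coefficients.csv")
        report = precision_report(
            {"point": fits["point"], "band": fits["band"]}, fits["joint"])
        report.to_csv(out / "precision_report.csv", index=False)
        cells = relative_bci_difference(
            pd.concat([fits["point"].site_year_bci(q)
                       for q in ("phi", "N", "G")]),
            pd.concat([fits["joint"].site_year_bci(q)
                       for q in ("phi", "N", "G")]))
        plot_precision(cells, out / "precision_violin.png")
        return report

    stage("compare", compare)

    def cost():
        specs = {
            "point": PointCostSpec(**scenario.costs.get("point", {})),
            "band": BandCostSpec(**scenario.costs.get("band", {})),
            "joint": JointCostSpec(**scenario.costs.get("joint", {})),
        }
        totals = {"point": cost_detection(specs["point"]),
                  "band": cost_banding(specs["band"]),
                  "joint": cost_joint(specs["joint"])}
        report = {"totals": {k: float(v) for k, v in totals.items()},
                  "components": {k: {kk: float(vv) for kk, vv in
                                     asdict(s).items()}
                                 for k, s in specs.items()}}
        with open(out / "cost_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return totals

    log["costs"] = {k: float(v) for k, v in stage("cost", cost).items()}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    return {"fits": fits, "log": log}
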