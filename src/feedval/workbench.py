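"""Pipeline configuration, report writers, and stage orchestration.

Ties the analysis modules into a reproducible run: simulate the three
trials, estimate diet and ingredient energy values, phosphorus and
amino-acid digestibilities, evaluate the prediction-equation registry on
the packaged ingredient table, and judge predictions against observed in
vivo means.  Every report is plain CSV with a provenance header (package
version, seed, configuration hash); the same configuration and seed
yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .accuracy import assess
from .composition import load_reference_ingredients
from .digestibility import (
    DEFAULT_BASAL_P_LOSS_MG_PER_KG_DMI,
    aid_sid,
    attd_p,
    basal_endogenous_aa,
    digesta_records_to_df,
    sttd_from_attd,
)
from .energy_balance import collection_records_to_df
from .prediction import PredictionOutcome, predict_all
from .simulate import (
    NoiseSpec,
    default_scenario,
    recover_diet_energy,
    recover_ingredient_energy,
    simulate_energy_trial,
    simulate_ileal_trial,
    simulate_p_trial,
)

log = logging.getLogger("feedval")

STAGES = ("simulate", "energy", "phosphorus", "amino-acids", "predict", "assess")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    outdir: str = "feedval-out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    estimator: str = "marker"          # or "total"
    basal_p_loss_mg: float = DEFAULT_BASAL_P_LOSS_MG_PER_KG_DMI
    equations: Optional[tuple[str, ...]] = None   # None = all registered
    confidence_level: float = 0.95
    n_pigs_per_diet: int = 9
    marker_cv: float = 0.05
    ge_cv: float = 0.05
    conc_cv: float = 0.05
    zero_ndf_for: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        if self.estimator not in ("marker", "total"):
            raise ValueError("estimator must be 'marker' or 'total'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "equations", "zero_ndf_for"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "equations", "zero_ndf_for"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @property
    def config_hash(self) -> str:
        # provenance of the scientific settings; where reports land is not one
        d = self.as_dict()
        d.pop("outdir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_report(df: pd.DataFrame, path: Path, cfg: RunConfig, title: str) -> None:
    header = (
        f"# feedval {__version__} | {title} | seed={cfg.seed} "
        f"| config={cfg.config_hash}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    log.info("wrote %s", path)


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the requested stages; returns each stage's report frame.

    Stage order is fixed (simulate -> energy -> phosphorus -> amino-acids
    -> predict -> assess); estimation stages simulate their input records
    on demand when the simulate stage was not requested.  An empty stage
    list is a warned no-op.
    """
    if not cfg.stages:
        warnings.warn("no stages requested; nothing to do", stacklevel=2)
        return {}
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    noise = NoiseSpec(cfg.marker_cv, cfg.ge_cv, cfg.conc_cv)
    sc = default_scenario(seed=cfg.seed, n_pigs_per_diet=cfg.n_pigs_per_diet, noise=noise)
    reports: dict[str, pd.DataFrame] = {}

    current_stage = "setup"

    def stage_wanted(name: str) -> bool:
        nonlocal current_stage
        if name in cfg.stages:
            current_stage = name
            return True
        return False

    try:
        if stage_wanted("simulate"):
            for label, df in (
                ("energy_records", collection_records_to_df(simulate_energy_trial(sc))),
                ("p_records", collection_records_to_df(simulate_p_trial(sc))),
                ("ileal_records", digesta_records_to_df(simulate_ileal_trial(sc))),
            ):
                _write_report(df, outdir / f"{label}.csv", cfg, label)
                reports[label] = df

        if stage_wanted("energy"):
            records = simulate_energy_trial(sc)
            diet_ge = {d.name: d.ge for d in sc.energy_diets}
            diets = recover_diet_energy(records, diet_ge, method=cfg.estimator)
            ingredients = recover_ingredient_energy(sc, records, method=cfg.estimator)
            rows = [
                {"item": f"diet:{name}", "de_kcal_kg_dm": e.de, "me_kcal_kg_dm": e.me,
                 "de_ge": e.de_ge, "me_ge": e.me_ge, "me_de": e.me_de}
                for name, e in sorted(diets.items())
            ] + [
                {"item": f"ingredient:{name}", "de_kcal_kg_dm": e.de,
                 "me_kcal_kg_dm": e.me, "de_ge": None, "me_ge": None, "me_de": e.me_de}
                for name, e in sorted(ingredients.items())
            ]
            df = pd.DataFrame(rows)
            _write_report(df, outdir / "energy_summary.csv", cfg, "diet and ingredient DE/ME")
            reports["energy"] = df

        if stage_wanted("phosphorus"):
            records = simulate_p_trial(sc)
            rows = []
            for diet in sc.p_diets:
                recs = [r for r in records if r.diet == diet.name]
                attds = [attd_p(r, diet.p_pct_dm) for r in recs]
                sttds = [
                    sttd_from_attd(a, diet.p_pct_dm * 10.0, cfg.basal_p_loss_mg)
                    for a in attds
                ]
                s = pd.Series(attds)
                rows.append(
                    {"diet": diet.name, "n": len(recs),
                     "attd_p_pct": s.mean(), "attd_sd": s.std(ddof=1),
                     "sttd_p_pct": float(pd.Series(sttds).mean())}
                )
            df = pd.DataFrame(rows)
            _write_report(df, outdir / "phosphorus_summary.csv", cfg, "ATTD/STTD of P")
            reports["phosphorus"] = df

        if stage_wanted("amino-acids"):
            records = simulate_ileal_trial(sc)
            nfree = [r for r in records if r.diet == "n_free"]
            endogenous = basal_endogenous_aa(nfree)
            rows = []
            for diet in sc.ileal_diets:
                if diet.aid is None:
                    continue
                recs = [r for r in records if r.diet == diet.name]
                for res in aid_sid(recs, endogenous):
                    rows.append(
                        {"diet": diet.name, "nutrient": res.nutrient,
                         "aid_pct": res.apparent, "sid_pct": res.standardized,
                         "endogenous_g_kg_dmi": res.basal_endogenous_loss,
                         "n": res.n, "sd": res.sd}
                    )
            df = pd.DataFrame(rows)
            _write_report(df, outdir / "amino_acid_summary.csv", cfg, "AID/SID of CP and AA")
            reports["amino-acids"] = df

        if stage_wanted("predict") or stage_wanted("assess"):
            comps = [
                c for name, c in load_reference_ingredients().items() if name != "corn"
            ]
            df = predict_all(comps, eq_ids=list(cfg.equations) if cfg.equations else None,
                             zero_ndf_for=cfg.zero_ndf_for)
            if stage_wanted("predict"):
                _write_report(df, outdir / "predictions.csv", cfg, "DE/ME predictions")
                reports["predict"] = df

        if stage_wanted("assess"):
            observed = pd.read_csv(
                Path(__file__).parent / "data" / "observed_energy.csv", comment="#"
            )
            rows = []
            for _, obs in observed.iterrows():
                preds = df[
                    (df["ingredient"] == obs["ingredient"])
                    & (df["output"] == obs["quantity"])
                    & df["predicted"].notna()
                ]
                outcomes = [
                    PredictionOutcome(r["equation"], r["ingredient"], r["predicted"],
                                      r["output"])
                    for _, r in preds.iterrows()
                ]
                for v in assess(obs["observed_mean"], obs["margin"], outcomes):
                    rows.append(
                        {"ingredient": v.ingredient, "quantity": obs["quantity"],
                         "equation": v.equation_id, "predicted": v.predicted,
                         "observed_mean": v.observed_mean, "lower": v.lower,
                         "upper": v.upper, "within": v.within,
                         "signed_error": v.signed_error}
                    )
            vdf = pd.DataFrame(rows)
            _write_report(vdf, outdir / "verdicts.csv", cfg, "prediction accuracy verdicts")
            reports["assess"] = vdf
    except Exception as err:  # annotate with the failing stage for the operator
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {err}") from err

    return reports
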