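"""End-to-end pipeline: phantoms -> PVMs -> synthesis -> experiments -> analyses.

Each stage writes its artifacts plus one manifest row (path, stage, seed,
sha256) so a run is fully auditable; re-running with the same config
reproduces every non-log output bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import features, phantoms, psychophys, pvm, synthesis
from .exceptions import ConfigError, MammotexError
from .io import sha256_file, write_image, write_table
from .seeds import child_seed

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("mammotex")

_ALL_STAGES = ("phantoms", "pvm", "synthesis", "experiments", "analyses")


@dataclass
class RunConfig:
    """Validated top-level run configuration."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    n_per_class: int = 1
    phantom_size: int = 64
    pvm_size: int = 48
    synthesis_iters: int = 150
    synthesis_tol: float = 1e-6
    n_stimulus_pairs: int = 4
    min_presentations: int = 10
    n_subjects_exp1: int = 14
    n_subjects_exp2: int = 12
    network_config: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        # keep canonical execution order regardless of listing order
        self.stages = tuple(s for s in _ALL_STAGES if s in self.stages)
        if self.network_config is not None:
            self.network_config = Path(self.network_config)
            if not self.network_config.exists():
                raise ConfigError(f"network config not found: {self.network_config}")


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "out_dir" not in doc:
        raise ConfigError(f"{path}: run config needs an out_dir")
    doc["stages"] = tuple(doc.get("stages", _ALL_STAGES))
    return RunConfig(**doc)


class _Manifest:
    def __init__(self, config: RunConfig):
        self.config = config
        self.rows = []

    def record(self, path: Path, stage: str):
        self.rows.append({
            "path": str(path.relative_to(self.config.out_dir)),
            "stage": stage,
            "master_seed": self.config.seed,
            "sha256": sha256_file(path),
        })

    def write(self) -> Path:
        path = self.config.out_dir / "manifest.csv"
        pd.DataFrame(self.rows, columns=["path", "stage", "master_seed", "sha256"]
                     ).to_csv(path, index=False)
        return path


def _build_net(config: RunConfig):
    if config.network_config is not None:
        return features.build_network(features.load_network_config(config.network_config))
    return features.build_network(features.desk_config(weight_seed=child_seed(config.seed, 1000)))


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the selected stages in order; returns the manifest table."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    state: dict = {}
    try:
        for stage in config.stages:
            log.info("stage %s", stage)
            _STAGE_FNS[stage](config, manifest, state)
    except MammotexError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    manifest.write()
    return pd.DataFrame(manifest.rows)


def _stage_phantoms(config, manifest, state):
    cohort = phantoms.generate_cohort(config.n_per_class, config.phantom_size,
                                      seed=config.seed)
    pdir = config.out_dir / "phantoms"
    pdir.mkdir(exist_ok=True)
    rows = []
    for k, ph in enumerate(cohort):
        img_path = write_image(ph.image, pdir / f"phantom_{k:03d}.png", depth=16)
        mask_path = write_image(ph.roi_mask.astype(float), pdir / f"mask_{k:03d}.png",
                                depth=8)
        manifest.record(img_path, "phantoms")
        manifest.record(mask_path, "phantoms")
        rows.append({"id": f"phantom_{k:03d}", "class": ph.class_label, "seed": ph.seed})
    table = write_table(pd.DataFrame(rows), pdir / "phantoms.csv")
    manifest.record(table, "phantoms")
    state["cohort"] = cohort


def _stage_pvm(config, manifest, state):
    cohort = state.get("cohort") or phantoms.generate_cohort(
        config.n_per_class, config.phantom_size, seed=config.seed)
    vdir = config.out_dir / "pvm"
    vdir.mkdir(exist_ok=True)
    records, rows = [], []
    for k, ph in enumerate(cohort):
        sid = f"phantom_{k:03d}"
        if ph.class_label == "normal":
            rec = pvm.extract_pvm_salient(ph.image, config.pvm_size, ph.class_label, sid)
        else:
            rec = pvm.extract_pvm_roi(ph.image, ph.roi_mask, config.pvm_size,
                                      ph.class_label, sid)
        if isinstance(rec, pvm.Skip):
            rows.append({"source": sid, "class": ph.class_label, "provenance": "",
                         "center_row": -1, "center_col": -1, "skip_reason": rec.reason})
            continue
        path = write_image(rec.crop, vdir / f"pvm_{k:03d}.png", depth=16)
        manifest.record(path, "pvm")
        rows.append({"source": sid, "class": rec.class_label,
                     "provenance": rec.provenance, "center_row": rec.center[0],
                     "center_col": rec.center[1], "skip_reason": ""})
        records.append((k, rec))
    table = write_table(pd.DataFrame(rows), vdir / "pvm.csv")
    manifest.record(table, "pvm")
    state["pvms"] = records


def _stage_synthesis(config, manifest, state):
    if "pvms" not in state:
        _stage_pvm(config, manifest, state)
    net = _build_net(config)
    sdir = config.out_dir / "synthesis"
    sdir.mkdir(exist_ok=True)
    outputs = []
    for k, rec in state["pvms"]:
        opts = synthesis.SynthesisOptions(
            max_iters=config.synthesis_iters, tol=config.synthesis_tol,
            init_seed=child_seed(config.seed, 2000, k),
        )
        result = synthesis.synthesize(net, rec.crop, opts)
        path = write_image(result.image, sdir / f"synth_{k:03d}.png", depth=16)
        manifest.record(path, "synthesis")
        traj = pd.DataFrame({"iteration": range(len(result.loss_trajectory)),
                             "loss": result.loss_trajectory})
        tpath = write_table(traj, sdir / f"loss_{k:03d}.csv")
        manifest.record(tpath, "synthesis")
        outputs.append((k, rec, result))
    state["synth"] = outputs
    state["network"] = net


def _stimulus_set(config) -> psychophys.StimulusSet:
    classes = ["normal", "normal", "cancer", "cancer"]
    pairs = tuple(
        (f"O{k + 1}", f"S{k + 1}", classes[k % len(classes)])
        for k in range(config.n_stimulus_pairs)
    )
    return psychophys.StimulusSet(pairs)


def _stage_experiments(config, manifest, state):
    stim = _stimulus_set(config)
    edir = config.out_dir / "experiments"
    edir.mkdir(exist_ok=True)
    sched1 = psychophys.make_schedule(stim, config.min_presentations, 1,
                                      seed=child_seed(config.seed, 3001))
    observers1 = [
        psychophys.ObserverModel(kind="chance", seed=child_seed(config.seed, 3100, k))
        for k in range(config.n_subjects_exp1)
    ]
    table1 = psychophys.simulate_panel(sched1, observers1)
    p1 = write_table(table1.trials, edir / "experiment1.csv")
    manifest.record(p1, "experiments")

    sched2 = psychophys.make_schedule(stim, config.min_presentations, 2,
                                      seed=child_seed(config.seed, 3002))
    observers2 = [
        psychophys.ObserverModel(kind="rater", seed=child_seed(config.seed, 3200, k))
        for k in range(config.n_subjects_exp2)
    ]
    table2 = psychophys.simulate_panel(sched2, observers2)
    p2 = write_table(table2.trials, edir / "experiment2.csv")
    manifest.record(p2, "experiments")
    state["stimuli"] = stim
    state["exp1"] = table1
    state["exp2"] = table2


def _stage_analyses(config, manifest, state):
    if "exp1" not in state:
        _stage_experiments(config, manifest, state)
    adir = config.out_dir / "analyses"
    adir.mkdir(exist_ok=True)
    dp = psychophys.dprime(state["exp1"])
    manifest.record(write_table(dp.table, adir / "dprime.csv"), "analyses")

    rdm = psychophys.build_rdm(state["exp2"])
    rdm_df = pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels)
    rpath = adir / "rdm.csv"
    rdm_df.to_csv(rpath)
    manifest.record(rpath, "analyses")

    # congruity between split-half subject panels
    trials = state["exp2"].trials
    subjects = sorted(trials["subject"].unique())
    half = len(subjects) // 2
    rdm_a = psychophys.build_rdm(psychophys.ResponseTable(
        trials[trials["subject"].isin(subjects[:half])], 2, state["stimuli"]))
    rdm_b = psychophys.build_rdm(psychophys.ResponseTable(
        trials[trials["subject"].isin(subjects[half:])], 2, state["stimuli"]))
    rho, p = psychophys.rdm_congruity(rdm_a, rdm_b, seed=child_seed(config.seed, 4000))
    t, tp, df_ = psychophys.paired_rating_test(state["exp2"])
    summary = pd.DataFrame([
        {"analysis": "rdm_congruity_split_half", "statistic": rho, "p": p, "df": ""},
        {"analysis": "paired_rating_t", "statistic": t, "p": tp, "df": df_},
    ])
    manifest.record(write_table(summary, adir / "summary.csv"), "analyses")

    tree = psychophys.hca(rdm)
    npath = adir / "hca.nwk"
    npath.write_text(tree.to_newick() + "\n", encoding="utf-8")
    manifest.record(npath, "analyses")


_STAGE_FNS = {
    "phantoms": _stage_phantoms,
    "pvm": _stage_pvm,
    "synthesis": _stage_synthesis,
    "experiments": _stage_experiments,
    "analyses": _stage_analyses,
}
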