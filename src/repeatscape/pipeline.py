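"""Orchestration: curate -> fit -> entropy -> landscape -> kl as one
reproducible, idempotent pipeline driven by a YAML/dict config.

Each stage records the hash of its configuration and upstream artifacts in a
run manifest; re-running with an unchanged config skips up-to-date stages.
The entropy stage writes a summary table (variant x entropy +- errors) and,
when the four relevant variants are present, the entropy-decomposition
contributions (within-repeat interactions S_1 - S_ir, phylogenic similarity
S_ir - S_ir_lambda, repeat-repeat interactions S_ir_lambda - S_full, and the
redundancy S_ir - S_ir_lambda - S_2 + S_full), computed from the variant
entropies so the decomposition identities hold exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    Alignment,
    cluster_weights,
    compute_observables,
    read_alignment,
    remove_gappy_columns,
    write_alignment,
)
from .divergence import kl_divergence
from .entropy import (
    entropy_error_independent,
    entropy_thermodynamic,
    estimate_learning_bias,
    random_model_entropy_bits,
)
from .fitting import VARIANTS, FitConfig, fit_variant_suite
from .landscape import basin_decomposition, consensus_energy, minima_clustering
from .modelio import load_model, save_model
from .synthetic import PlantedSpec, make_planted_alignment, make_planted_model

_FIT_KEYS = set(FitConfig().__dict__)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)  # name -> {hash, outputs, seconds, skipped}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "config": self.config,
                       "stages": self.stages}, fh, indent=2, default=str)


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> dict:
    """Schema check before any compute; returns the config with defaults filled."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    out = dict(cfg)
    if "workdir" not in out:
        raise ValueError("config requires 'workdir'")
    out.setdefault("seed", 0)
    data = out.get("data", {})
    if not isinstance(data, dict) or (("fasta" in data) == ("planted" in data)):
        raise ValueError("config 'data' must give exactly one of 'fasta' or 'planted'")
    if "fasta" in data:
        if "L" not in data:
            raise ValueError("'data.fasta' requires 'data.L'")
        if not Path(data["fasta"]).exists():
            raise FileNotFoundError(f"alignment not found: {data['fasta']}")
    out.setdefault("curate", {})
    out.setdefault("variants", list(VARIANTS))
    bad = set(out["variants"]) - set(VARIANTS)
    if bad:
        raise ValueError(f"unknown variants: {sorted(bad)}")
    out.setdefault("fit", {})
    badf = set(out["fit"]) - _FIT_KEYS
    if badf:
        raise ValueError(f"unknown fit options: {sorted(badf)}")
    out.setdefault("entropy", {})
    out.setdefault("landscape", {"enabled": False})
    out.setdefault("kl", None)
    return out


def _stage(manifest: RunManifest, name: str, stage_hash: str, outputs: list[Path]):
    """True if the stage can be skipped (hash unchanged, outputs present)."""
    prev = manifest.stages.get(name)
    if prev and prev.get("hash") == stage_hash and all(Path(p).exists() for p in prev["outputs"]):
        prev["skipped"] = True
        return True
    return False


def run_pipeline(config) -> RunManifest:
    """Execute the configured stages in dependency order; see module docstring."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    work = Path(cfg["workdir"])
    work.mkdir(parents=True, exist_ok=True)
    manifest_path = work / "manifest.json"
    manifest = RunManifest(config=cfg)
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        manifest.stages = old.get("stages", {})
    seed = int(cfg["seed"])

    # -- data ---------------------------------------------------------------
    t0 = time.time()
    data_cfg = cfg["data"]
    aln_path = work / "alignment.fa"
    data_hash = _hash_obj({"data": data_cfg, "seed": seed})
    if not _stage(manifest, "data", data_hash, [aln_path]):
        if "planted" in data_cfg:
            spec = PlantedSpec(**data_cfg["planted"])
            planted = make_planted_model(spec)
            save_model(planted, work / "planted_model.h5")
            aln = make_planted_alignment(planted, int(data_cfg.get("n_sequences", 5000)),
                                         seed=seed)
            write_alignment(aln, aln_path)
        else:
            aln = read_alignment(data_cfg["fasta"], int(data_cfg["L"]))
            write_alignment(aln, aln_path)
        manifest.stages["data"] = {"hash": data_hash, "outputs": [str(aln_path)],
                                   "seconds": time.time() - t0, "skipped": False}
    if "planted" in data_cfg:
        aln = read_alignment(aln_path, PlantedSpec(**data_cfg["planted"]).L,
                             alphabet=_planted_alphabet(data_cfg))
    else:
        aln = read_alignment(aln_path, int(data_cfg["L"]))

    # -- curate -------------------------------------------------------------
    t0 = time.time()
    cur = cfg["curate"]
    if cur.get("max_gap_frac") is not None:
        aln, _ = remove_gappy_columns(aln, float(cur["max_gap_frac"]))
    if cur.get("identity") is not None:
        aln.weights = cluster_weights(aln, float(cur["identity"]))
    obs = compute_observables(aln)
    manifest.stages["curate"] = {"hash": _hash_obj(cur), "outputs": [],
                                 "seconds": time.time() - t0, "skipped": False}

    # -- fit ----------------------------------------------------------------
    t0 = time.time()
    variants = list(cfg["variants"])
    fit_cfg = FitConfig(**{"seed": seed, **cfg["fit"]})
    fit_hash = _hash_obj({"fit": cfg["fit"], "variants": variants,
                          "upstream": [_hash_obj(cfg["data"]), _hash_obj(cur)], "seed": seed})
    model_paths = {v: work / f"model_{v}.h5" for v in variants}
    if not _stage(manifest, "fit", fit_hash, list(model_paths.values())):
        models, reports = fit_variant_suite(obs, fit_cfg, variants=variants)
        for v, m in models.items():
            save_model(m, model_paths[v])
        with open(work / "fit_reports.json", "w") as fh:
            json.dump(
                {v: (None if r is None else {
                    "iterations": r.iterations, "converged": r.converged,
                    "max_err_f1": r.max_err_f1, "max_err_f2": r.max_err_f2,
                    "max_err_pid": r.max_err_pid})
                 for v, r in reports.items()}, fh, indent=2)
        manifest.stages["fit"] = {"hash": fit_hash,
                                  "outputs": [str(p) for p in model_paths.values()],
                                  "seconds": time.time() - t0, "skipped": False}
    models = {v: load_model(p) for v, p in model_paths.items()}

    # -- entropy ------------------------------------------------------------
    t0 = time.time()
    ent_cfg = cfg["entropy"]
    n_ent = int(ent_cfg.get("n_samples", fit_cfg.n_samples))
    grid = np.linspace(0.0, 1.0, int(ent_cfg.get("grid", 51)))
    thinning = int(ent_cfg.get("thinning", fit_cfg.thinning))
    summary_path = work / "entropy_summary.tsv"
    ent_hash = _hash_obj({"entropy": ent_cfg, "fit": fit_hash, "seed": seed})
    if not _stage(manifest, "entropy", ent_hash, [summary_path]):
        rows = []
        S_bits: dict[str, float] = {}
        for v in variants:
            m = models[v]
            if v == "E_rand":
                s_bits, mc_err, bias = random_model_entropy_bits(m.n_sites, m.q), 0.0, 0.0
            elif v == "E_1":
                # closed form: no sampling needed for the independent model
                from .entropy import independent_entropy_nats, LN2
                s_bits = independent_entropy_nats(obs.f1) / LN2
                mc_err, bias = 0.0, 0.0
            else:
                res = entropy_thermodynamic(m, n=n_ent, alpha_grid=grid,
                                            thinning=thinning, seed=seed + 17)
                bias = estimate_learning_bias(m, obs, n=n_ent, thinning=thinning,
                                              seed=seed + 29)
                s_bits, mc_err = res.S_bits, res.mc_error_bits
            S_bits[v] = s_bits
            rows.append({"variant": v, "S_bits": s_bits, "mc_error_bits": mc_err,
                         "bias_error_bits": bias,
                         "finite_sample_error_bits": entropy_error_independent(obs) / np.log(2)})
        pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)
        decomp = {}
        if {"E_1", "E_ir", "E_ir_lambda", "E_full"} <= set(S_bits):
            decomp = {
                "within_repeat_S1_minus_Sir": S_bits["E_1"] - S_bits["E_ir"],
                "phylogenic_Sir_minus_Sirlam": S_bits["E_ir"] - S_bits["E_ir_lambda"],
                "repeat_repeat_Sirlam_minus_Sfull": S_bits["E_ir_lambda"] - S_bits["E_full"],
            }
            if "E_2" in S_bits:
                decomp["redundancy_Sir_minus_Sirlam_minus_S2_plus_Sfull"] = (
                    S_bits["E_ir"] - S_bits["E_ir_lambda"] - S_bits["E_2"] + S_bits["E_full"]
                )
        with open(work / "entropy_decomposition.json", "w") as fh:
            json.dump({"S_bits": S_bits, "decomposition": decomp}, fh, indent=2)
        manifest.stages["entropy"] = {"hash": ent_hash, "outputs": [str(summary_path)],
                                      "seconds": time.time() - t0, "skipped": False}

    # -- landscape ----------------------------------------------------------
    lsc = cfg["landscape"]
    if lsc.get("enabled"):
        t0 = time.time()
        variant = lsc.get("variant", "E_full")
        part_path = work / "basins.json"
        lsc_hash = _hash_obj({"landscape": lsc, "fit": fit_hash, "seed": seed})
        if not _stage(manifest, "landscape", lsc_hash, [part_path]):
            m = models[variant]
            part = basin_decomposition(m, aln.sequences, aln.weights,
                                       seed=int(lsc.get("seed", 0)))
            D, Z, sel = minima_clustering(part, float(lsc.get("coverage", 0.9)))
            np.savetxt(work / "minima_distances.tsv", D, fmt="%d", delimiter="\t")
            with open(part_path, "w") as fh:
                json.dump({
                    "n_minima": len(part.minima),
                    "S_conf_bits": part.S_conf_bits,
                    "P_b": part.P_b.tolist(),
                    "minima_energies": part.energies.tolist(),
                    "consensus_energy": consensus_energy(m, obs),
                    "selected": sel.tolist(),
                    "linkage": None if Z is None else Z.tolist(),
                }, fh, indent=2)
            manifest.stages["landscape"] = {"hash": lsc_hash, "outputs": [str(part_path)],
                                            "seconds": time.time() - t0, "skipped": False}

    # -- kl -----------------------------------------------------------------
    if cfg["kl"]:
        t0 = time.time()
        klc = cfg["kl"]
        kl_path = work / "kl.json"
        kl_hash = _hash_obj({"kl": klc, "fit": fit_hash, "seed": seed})
        if not _stage(manifest, "kl", kl_hash, [kl_path]):
            res = kl_divergence(models[klc["model_a"]], models[klc["model_b"]],
                                n=int(klc.get("n_samples", n_ent)),
                                alpha_grid=grid, thinning=thinning, seed=seed + 43)
            with open(kl_path, "w") as fh:
                json.dump({"d_ab_bits": res.d_ab_bits, "d_ba_bits": res.d_ba_bits,
                           "err_ab_bits": res.err_ab_bits,
                           "err_ba_bits": res.err_ba_bits}, fh, indent=2)
            manifest.stages["kl"] = {"hash": kl_hash, "outputs": [str(kl_path)],
                                     "seconds": time.time() - t0, "skipped": False}

    manifest.save(manifest_path)
    return manifest


def _planted_alphabet(data_cfg: dict) -> str:
    from .alignment import _symbol_alphabet

    return _symbol_alphabet(PlantedSpec(**data_cfg["planted"]).q)
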