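"""End-to-end orchestration: simulate -> QC -> RF -> tuning -> axis -> decode
-> selectivity -> report.

A :class:`RunConfig` fully determines a run: stimulus parameters, analysis
windows and thresholds, and the synthetic world (areas, unit counts, gains).
All randomness flows from one seed through per-stage spawned generators, so
two runs with equal configs produce identical outputs. Artifacts are CSV and
JSON files under the run directory, hashed into ``MANIFEST.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import axis as axis_mod
from . import decode as decode_mod
from . import qc as qc_mod
from . import receptive_fields as rf_mod
from . import selectivity as sel_mod
from . import tuning as tuning_mod
from .responses import response_tensor, time_resolved_rates
from .synthetic import (
    Session,
    extract_features,
    make_grating_schedule,
    make_image_schedule,
    make_object_bank,
    make_population,
    make_sparse_noise_schedule,
    make_texture_bank,
    simulate_session,
)

__all__ = ["RunConfig", "run_pipeline", "hierarchy_summary"]


@dataclass
class RunConfig:
    """Structured configuration for a full synthetic run.

    Defaults give a demo-scale world (5 areas x 24 units, reduced image
    counts and feature dimension) that completes in minutes on one CPU;
    paper-scale stimulus counts are the generator defaults and can be
    restored per field.
    """

    seed: int = 0
    areas: tuple[str, ...] = ("V1", "V2", "TP", "TI-ITi", "ITr")
    units_per_area: int = 24
    # stimuli
    sparse_noise_frames: int = 1200
    grating_repeats: int = 5
    texture_families: int = 15
    texture_samples_per_family: int = 2
    n_objects: int = 240
    n_faces: int = 60
    object_repeats: int = 6
    n_aux_images: int = 400
    image_px: int = 48
    feature_dim: int = 512
    n_pcs: int = 50
    # analysis windows and thresholds
    response_window: tuple[float, float] = (0.0, 0.1)
    baseline_window: tuple[float, float] = (-0.05, 0.0)
    responsive_sd: float = 5.0
    rf_quality_threshold: float = 5.0
    face_t_threshold: float = 5.0
    texture_alpha: float = 0.01
    texture_bin_s: float = 0.01
    # texture modulation in the synthetic world (area -> gain Hz, onset s)
    texture_gains: dict = field(
        default_factory=lambda: {"V1": (6.0, 0.090), "V2": (10.0, 0.045)}
    )
    # decoding
    decode_n_cells: int = 20
    gnb_cells_grid: tuple[int, ...] = (5, 15)
    gnb_neuron_resamples: int = 10
    gnb_split_resamples: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("areas", "gnb_cells_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        for key in ("response_window", "baseline_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["texture_gains"] = {k: list(v) for k, v in d["texture_gains"].items()}
        return d


def _spawn(seed: int, stage: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(h,)))


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def hierarchy_summary(
    rf_table: pd.DataFrame, latency_table: pd.DataFrame, min_units: int = 3
) -> pd.DataFrame:
    """Per-area median RF size (ON and OFF) and latency, with rank agreement.

    Areas lacking receptive fields (fewer than ``min_units`` fitted units,
    like TP) are kept in the latency ranking but excluded from the size
    ranking. The returned frame carries the Spearman correlation between the
    size and latency orderings in ``attrs['rank_correlation']``.
    """
    rows = []
    for area in sorted(set(latency_table["area"])):
        lat = latency_table.loc[latency_table["area"] == area, "latency_s"]
        row = dict(area=area, median_latency_s=float(lat.median()) if len(lat) else np.nan)
        for pol in ("ON", "OFF"):
            sel = rf_table[(rf_table["area"] == area) & (rf_table["polarity"] == pol) & rf_table["has_rf"]]
            row[f"median_size_{pol.lower()}_deg"] = (
                float(sel["size_deg"].median()) if len(sel) >= min_units else np.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    size = out[["median_size_on_deg", "median_size_off_deg"]].mean(axis=1)
    ok = size.notna() & out["median_latency_s"].notna()
    if ok.sum() >= 2:
        rho, _ = stats.spearmanr(size[ok], out.loc[ok, "median_latency_s"])
        out.attrs["rank_correlation"] = float(rho)
    else:
        out.attrs["rank_correlation"] = float("nan")
    return out


def _build_world(cfg: RunConfig):
    """Schedules, banks, features and ground-truth neurons for one run."""
    seed = cfg.seed
    frames = make_sparse_noise_schedule(
        n_frames=cfg.sparse_noise_frames, seed=_stage_seed(seed, "sparse")
    )
    t = frames[-1].onset_s + frames[-1].duration_s + 2.0
    _, grating_events = make_grating_schedule(
        n_repeats=cfg.grating_repeats, t0=t, seed=_stage_seed(seed, "gratings")
    )
    t = float(grating_events["onset_s"].max()) + 2.0
    texture_bank = make_texture_bank(
        cfg.texture_families,
        cfg.texture_samples_per_family,
        (cfg.image_px, cfg.image_px),
        seed=_stage_seed(seed, "textures"),
    )
    texture_events = make_image_schedule(
        texture_bank.image_ids, 5, "texture_noise", t0=t, seed=_stage_seed(seed, "tex_sched")
    )
    t = float(texture_events["onset_s"].max()) + 2.0
    object_bank = make_object_bank(
        cfg.n_objects, cfg.n_faces, (cfg.image_px, cfg.image_px), seed=_stage_seed(seed, "objects")
    )
    object_events = make_image_schedule(
        object_bank.image_ids,
        cfg.object_repeats,
        "objects",
        t0=t,
        block_gap_s=2.0,
        seed=_stage_seed(seed, "obj_sched"),
    )
    feats = extract_features(
        object_bank,
        layers=(4,),
        n_pcs=cfg.n_pcs,
        out_dim=cfg.feature_dim,
        seed=_stage_seed(seed, "features"),
    )["layer4"]

    aux_bank = make_object_bank(
        int(cfg.n_aux_images * 0.85),
        cfg.n_aux_images - int(cfg.n_aux_images * 0.85),
        (cfg.image_px, cfg.image_px),
        seed=_stage_seed(seed, "aux"),
    )
    aux_feats = extract_features(
        aux_bank, layers=(4,), n_pcs=cfg.n_pcs, out_dim=cfg.feature_dim,
        seed=_stage_seed(seed, "features"),
    )["layer4"]

    neurons = []
    for i, area in enumerate(cfg.areas):
        gain, onset = cfg.texture_gains.get(area, (0.0, None))
        neurons.extend(
            make_population(
                cfg.units_per_area,
                area=area,
                n_pcs=cfg.n_pcs,
                seed=_stage_seed(seed, f"pop:{area}"),
                texture_gain=gain,
                texture_latency=onset,
                n_blocks=cfg.object_repeats,
                unit_id_start=1000 * i,
            )
        )
    session = Session(
        sparse_noise=frames,
        grating_events=grating_events,
        texture_events=texture_events,
        object_events=object_events,
        texture_bank=texture_bank,
        object_bank=object_bank,
        object_features=feats,
    )
    return session, neurons, feats, aux_feats, texture_bank, object_bank


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write tabular artifacts plus a manifest.

    Returns the report dictionary (also written to ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_log: list[dict] = []

    def _log(stage: str, t0: float) -> None:
        stage_log.append(dict(stage=stage, wall_s=round(time.time() - t0, 2)))

    t0 = time.time()
    session, neurons, feats, aux_feats, texture_bank, object_bank = _build_world(cfg)
    spikes, events, sim_log = simulate_session(neurons, session, seed=_stage_seed(cfg.seed, "sim"))
    spikes.to_csv(out / "spikes.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    _log("simulate", t0)

    area_of = {n.unit_id: n.area for n in neurons}
    from .responses import spikes_by_unit

    per_unit = spikes_by_unit(spikes)

    # ---- QC: responsiveness per class, latency ----
    t0 = time.time()
    events_by_class = {
        "gratings": session.grating_events,
        "texture_noise": session.texture_events,
        "objects": session.object_events,
    }
    qc_table = qc_mod.responsiveness_table(
        spikes, events_by_class, cfg.responsive_sd, cfg.response_window, cfg.baseline_window
    )
    qc_table.to_csv(out / "qc.csv", index=False)
    lat_events = pd.concat([session.grating_events, session.texture_events], ignore_index=True)
    lat_rows = []
    for unit, times in per_unit.items():
        est = qc_mod.half_peak_latency(times, lat_events, unit_id=unit)
        if est.passes_peak_test and est.half_peak_latency is not None:
            lat_rows.append(dict(unit_id=unit, area=area_of[unit], latency_s=est.half_peak_latency))
    latency_table = pd.DataFrame(lat_rows)
    latency_table.to_csv(out / "latency.csv", index=False)
    _log("qc", t0)

    # ---- receptive fields ----
    t0 = time.time()
    rf_rows = []
    for unit, times in per_unit.items():
        fits = rf_mod.map_receptive_field(times, session.sparse_noise, cfg.response_window, unit)
        for pol, fit in fits.items():
            rf_rows.append(
                dict(
                    unit_id=unit,
                    area=area_of[unit],
                    polarity=pol,
                    x0=fit.center[0],
                    y0=fit.center[1],
                    sigma_deg=fit.sigma,
                    amplitude=fit.amplitude,
                    baseline=fit.baseline,
                    quality=fit.quality,
                    has_rf=fit.has_rf,
                    size_deg=rf_mod.rf_size(fit) if fit.has_rf else np.nan,
                )
            )
    rf_table = pd.DataFrame(rf_rows)
    rf_table.to_csv(out / "rf.csv", index=False)
    _log("rf", t0)

    # ---- tuning and texture ----
    t0 = time.time()
    from .responses import response_matrix

    g_counts, g_units = response_matrix(spikes, session.grating_events, cfg.response_window)
    rate_scale = 1.0 / (cfg.response_window[1] - cfg.response_window[0])
    oris = session.grating_events["orientation"].to_numpy()
    sfs = session.grating_events["spatial_frequency"].to_numpy()
    tuning_rows = []
    for i, unit in enumerate(g_units):
        r = g_counts[i] * rate_scale
        ori_fit = tuning_mod.fit_orientation(oris, r, unit_id=unit)
        sf_fit = tuning_mod.fit_spatial_frequency(sfs, r, unit_id=unit)
        v_ori = tuning_mod.variance_explained_categorical(r, oris, "orientation")
        v_sf = tuning_mod.variance_explained_categorical(r, sfs, "spatial_frequency")
        tuning_rows.append(
            dict(
                unit_id=unit,
                area=area_of[unit],
                theta_pref=ori_fit.theta_pref,
                kappa=ori_fit.kappa,
                ori_included=ori_fit.included,
                f_pref=sf_fit.f_pref,
                sf_included=sf_fit.included,
                pct_ori=v_ori.pct_explained,
                pct_sf=v_sf.pct_explained,
            )
        )
    pd.DataFrame(tuning_rows).to_csv(out / "tuning.csv", index=False)

    tex_events = session.texture_events
    cat = {int(i): c for i, c in zip(texture_bank.image_ids, texture_bank.category)}
    is_tex = tex_events["stim_id"].map(lambda s: cat[int(s)] == "texture").to_numpy()
    divergence = {}
    for area in cfg.areas:
        units = [u for u in per_unit if area_of[u] == area]
        if len(units) < 10:  # divergence test needs >= 10 cells
            divergence[area] = None
            continue
        area_spikes = spikes[spikes["unit_id"].isin(units)]
        tex_rates, _, edges = time_resolved_rates(
            area_spikes, tex_events[is_tex], (0.0, 0.167), cfg.texture_bin_s
        )
        noi_rates, _, _ = time_resolved_rates(
            area_spikes, tex_events[~is_tex], (0.0, 0.167), cfg.texture_bin_s
        )
        div = tuning_mod.texture_divergence(
            tex_rates, noi_rates, edges[:-1], cfg.texture_alpha, area=area
        )
        divergence[area] = div.divergence_latency
    _log("tuning", t0)

    # ---- axis model ----
    t0 = time.time()
    tensor, t_units, t_imgs = response_tensor(spikes, session.object_events, cfg.response_window)
    reliab = axis_mod.explainable_variance(tensor, t_units)
    explainable = np.array([r.explainable for r in reliab])
    mean_resp = tensor.mean(axis=2)
    axis_rows = []
    for i, unit in enumerate(t_units):
        pa = axis_mod.fit_preferred_axis(
            mean_resp[i], feats.pc_scores, seed=_stage_seed(cfg.seed, f"axis:{unit}"), unit_id=unit
        )
        axis_rows.append(
            dict(
                unit_id=unit,
                area=area_of[unit],
                ev_cv=pa.ev_cv,
                explainable=explainable[i],
                axis_pc1=pa.axis[0],
                axis_pc2=pa.axis[1],
            )
        )
    axis_table = pd.DataFrame(axis_rows)
    axis_table.to_csv(out / "axis.csv", index=False)
    _log("axis", t0)

    # ---- decoding / reconstruction ----
    t0 = time.time()
    decode_rows = []
    recon_rows = []
    for area in cfg.areas:
        mask = np.array([area_of[u] == area for u in t_units])
        resp = mean_resp[mask].T  # images x cells
        n_cells = min(cfg.decode_n_cells, mask.sum())
        pcs = decode_mod.decode_pcs(
            resp,
            feats.pc_scores,
            n_cells=n_cells,
            n_resamples=5,
            seed=_stage_seed(cfg.seed, f"dec:{area}"),
            area=area,
        )
        for p in pcs[:10]:
            decode_rows.append(
                dict(area=area, pc=p.pc_index, fraction=p.fraction_explained, n_cells=n_cells)
            )
        mean_d, sd_d, _ = decode_mod.area_reconstruction_summary(
            resp,
            t_imgs,
            feats,
            aux_feats.features,
            aux_feats.image_ids,
            n_cells=n_cells,
            seed=_stage_seed(cfg.seed, f"recon:{area}"),
            area=area,
        )
        recon_rows.append(dict(area=area, mean_normalized_distance=mean_d, sd=sd_d))
    pd.DataFrame(decode_rows).to_csv(out / "decode_pcs.csv", index=False)
    recon_table = pd.DataFrame(recon_rows)
    recon_table.to_csv(out / "reconstruction.csv", index=False)
    _log("decode", t0)

    # ---- selectivity ----
    t0 = time.time()
    is_face = np.array(
        [object_bank.category[object_bank.index_of(int(i))] == "face" for i in t_imgs]
    )
    sel_rows = []
    for i, unit in enumerate(t_units):
        s = sel_mod.face_selectivity(mean_resp[i], is_face, unit_id=unit)
        sel_rows.append(
            dict(unit_id=unit, area=area_of[unit], t_score=s.t_score, fsi=s.fsi,
                 face_cell=s.face_cell, highly_selective=s.highly_selective)
        )
    sel_table = pd.DataFrame(sel_rows)
    sel_table.to_csv(out / "selectivity.csv", index=False)

    gnb_rows = []
    for area in cfg.areas:
        mask = np.array([area_of[u] == area for u in t_units])
        face_tensor = tensor[np.ix_(mask, np.flatnonzero(is_face))]
        curve = sel_mod.gnb_identity_decoding(
            face_tensor,
            list(cfg.gnb_cells_grid),
            n_neuron_resamples=cfg.gnb_neuron_resamples,
            n_split_resamples=cfg.gnb_split_resamples,
            n_images=min(201, is_face.sum()),
            seed=_stage_seed(cfg.seed, f"gnb:{area}"),
            area=area,
            stimulus_subset="faces",
        )
        for n_c, a, sd in zip(curve.n_cells_grid, curve.accuracy, curve.accuracy_sd):
            gnb_rows.append(
                dict(area=area, subset="faces", n_cells=int(n_c), accuracy=float(a),
                     sd=float(sd), n_classes=curve.n_classes)
            )
    pd.DataFrame(gnb_rows).to_csv(out / "identity_decoding.csv", index=False)
    _log("selectivity", t0)

    # ---- report ----
    t0 = time.time()
    hier = hierarchy_summary(rf_table, latency_table)
    hier.to_csv(out / "hierarchy.csv", index=False)
    resp_frac = (
        qc_table.drop_duplicates("unit_id").groupby("area")["visually_responsive"].mean()
    )
    report = dict(
        config=cfg.to_dict(),
        n_units=len(neurons),
        responsive_fraction={k: float(v) for k, v in resp_frac.items()},
        texture_divergence_latency_s=divergence,
        hierarchy_rank_correlation=hier.attrs["rank_correlation"],
        mean_normalized_distance={
            r["area"]: float(r["mean_normalized_distance"]) for _, r in recon_table.iterrows()
        },
        face_cell_fraction={
            a: float(g["face_cell"].mean()) for a, g in sel_table.groupby("area")
        },
        rate_clips=sim_log["rate_clips"],
        stages=stage_log,
        total_wall_s=round(time.time() - t_start, 2),
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    _write_hierarchy_figure(hier, out / "hierarchy.png")

    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name == "MANIFEST.json" or f.is_dir():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
    return report


def _write_hierarchy_figure(hier: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    size = hier[["median_size_on_deg", "median_size_off_deg"]].mean(axis=1)
    ax.scatter(hier["median_latency_s"] * 1000, size)
    for _, row in hier.iterrows():
        vals = [v for v in (row["median_size_on_deg"], row["median_size_off_deg"]) if np.isfinite(v)]
        s = np.mean(vals) if vals else np.nan
        if np.isfinite(s):
            ax.annotate(row["area"], (row["median_latency_s"] * 1000, s), fontsize=8)
    ax.set_xlabel("median half-peak latency (ms)")
    ax.set_ylabel("median RF size (deg FWHM)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
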