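"""End-to-end orchestration: generate → segment → measure → profile → stats → VAE.

A :class:`RunConfig` (loadable from YAML) names the internode archetypes,
seeds and stage parameters; :func:`run` executes the requested stages in
dependency order, writing every artifact (images, masks, CSV tables, model
checkpoints, morph frames) under the output directory. All randomness flows
from the named seeds, so identical configurations reproduce identical
artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import morphometry as mm
from . import radial
from . import segmentation as seg
from . import stats as st
from . import synthgen as sg
from . import vae as vm

__all__ = ["RunConfig", "run", "STAGES"]

log = logging.getLogger("culmvb")

STAGES = ("generate", "train-seg", "predict", "measure", "profile",
          "stats", "train-vae", "morph")

_DEPS = {
    "generate": (),
    "train-seg": ("generate",),
    "predict": ("generate", "train-seg"),
    "measure": ("generate",),
    "profile": ("measure",),
    "stats": ("measure",),
    "train-vae": ("measure",),
    "morph": ("measure", "train-vae"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (schema version 1)."""

    schema_version: int = 1
    out_dir: str = "culmvb_run"
    internodes: tuple[int, ...] = (2, 12, 22, 32)
    seeds: tuple[int, ...] = (1, 2, 3)
    stages: tuple[str, ...] = STAGES
    seg: seg.SegConfig = field(default_factory=seg.SegConfig)
    vae: vm.VAEConfig = field(default_factory=vm.VAEConfig)
    n_train_tiles: int = 30
    n_bins_area: int = radial.N_BINS_AREA
    n_bins_count: int = radial.N_BINS_COUNT
    moving_window: int = 25
    alpha: float = st.ALPHA_DEFAULT
    measure_from: str = "truth"  # "truth" or "prediction"
    anchor_positions: tuple[float, ...] = vm.ANCHOR_POSITIONS
    frames_per_segment: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("schema_version", 1) != 1:
            raise ValueError("unsupported config schema_version")
        seg_cfg = seg.SegConfig(**raw.pop("seg", {}))
        vae_cfg = vm.VAEConfig(**raw.pop("vae", {}))
        for key in ("internodes", "seeds", "stages", "anchor_positions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(seg=seg_cfg, vae=vae_cfg, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _key(internode: int, s: int) -> str:
    return f"internode{internode:02d}_seed{s}"


def _require(cfg: RunConfig, stage: str, done: set[str], out: Path) -> None:
    for dep in _DEPS[stage]:
        marker = out / f".stage_{dep}.json"
        if dep not in done and not marker.exists():
            raise RuntimeError(
                f"stage '{stage}' requires upstream stage '{dep}' "
                f"(no artifacts found in {out})"
            )


def _mark(stage: str, out: Path, info: dict) -> None:
    (out / f".stage_{stage}.json").write_text(json.dumps(info, indent=1))


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns a per-stage report dict."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    report: dict = {}
    done: set[str] = set()
    # execute in canonical order regardless of listing order
    for stage in [s for s in STAGES if s in config.stages]:
        _require(config, stage, done, out)
        log.info("stage %s", stage)
        report[stage] = _STAGE_FNS[stage](config, out)
        _mark(stage, out, {"ok": True})
        done.add(stage)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _iter_sections(config: RunConfig):
    for iid in config.internodes:
        arch = sg.make_archetype(iid)
        for s in config.seeds:
            yield iid, s, arch


def _stage_generate(config: RunConfig, out: Path) -> dict:
    d = out / "sections"
    d.mkdir(exist_ok=True)
    n = 0
    for iid, s, arch in _iter_sections(config):
        img, gt = sg.generate_section(arch, seed=s)
        key = _key(iid, s)
        cio.save_image8(img.pixels, d / f"{key}.png")
        cio.save_mask16(gt.instance_mask, d / f"{key}_instances.png")
        meta = dict(
            internode_id=iid, seed=s,
            epidermis_row=gt.tissue_frame.epidermis_row,
            pith_row=gt.tissue_frame.pith_row,
            pixel_size_um=img.pixel_size_um,
            wall_thickness_px=arch.wall_thickness_px,
            n_instances=int(gt.instance_mask.max()),
        )
        (d / f"{key}.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        n += 1
    return {"sections": n}


def _load_section(out: Path, iid: int, s: int):
    d = out / "sections"
    key = _key(iid, s)
    pixels = cio.load_image8(d / f"{key}.png")
    inst = cio.load_mask16(d / f"{key}_instances.png")
    meta = yaml.safe_load((d / f"{key}.yaml").read_text())
    frame = mm.TissueFrame(meta["epidermis_row"], meta["pith_row"])
    return pixels, inst, frame, meta


def _stage_train_seg(config: RunConfig, out: Path) -> dict:
    sections = []
    for iid, s, arch in _iter_sections(config):
        pixels, inst, frame, _ = _load_section(out, iid, s)
        sections.append(
            (sg.SectionImage(pixels),
             sg.GroundTruth(inst, (), frame))
        )
    tiles = seg.sample_training_tiles(
        sections, config.n_train_tiles, config.seg.tile_size, seed=config.seg.seed
    )
    model = seg.build_model(config.seg)
    model, hist = seg.train(model, tiles, config.seg)
    seg.save_model(model, str(out / "seg_model.npz"))
    hist.to_csv(out / "seg_history.csv", index=False)
    return {"final_loss": float(hist.loss.iloc[-1]),
            "final_accuracy": float(hist.accuracy.iloc[-1])}


def _stage_predict(config: RunConfig, out: Path) -> dict:
    model = seg.load_model(str(out / "seg_model.npz"))
    d = out / "predictions"
    d.mkdir(exist_ok=True)
    evals = []
    for iid, s, arch in _iter_sections(config):
        pixels, inst, frame, _ = _load_section(out, iid, s)
        pred = seg.predict(model, pixels, config.seg)
        cio.save_image8(pred.astype(float), d / f"{_key(iid, s)}_pred.png")
        ev = seg.evaluate(pred, inst)
        evals.append(dict(internode=iid, seed=s,
                          pixel_accuracy=ev.pixel_accuracy,
                          connection_errors=ev.connection_errors,
                          missed=ev.missed))
    df = pd.DataFrame(evals)
    df.to_csv(d / "evaluation.csv", index=False)
    return {"mean_pixel_accuracy": float(df.pixel_accuracy.mean())}


def _stage_measure(config: RunConfig, out: Path) -> dict:
    d = out / "measurements"
    d.mkdir(exist_ok=True)
    frames = []
    for iid, s, arch in _iter_sections(config):
        pixels, inst, frame, _ = _load_section(out, iid, s)
        if config.measure_from == "prediction":
            pred = cio.load_image8(out / "predictions" / f"{_key(iid, s)}_pred.png")
            labels = mm.label_components(pred > 0.5, 8)
        else:
            labels = inst
        recs = mm.measure_all(labels, frame, exclude_border=True)
        df = mm.records_to_frame(recs)
        df.insert(0, "internode", iid)
        df.insert(1, "seed", s)
        frames.append(df)
    all_df = pd.concat(frames, ignore_index=True)
    all_df.to_csv(d / "bundles.csv", index=False)
    return {"bundles": int(len(all_df))}


def _stage_profile(config: RunConfig, out: Path) -> dict:
    d = out / "profiles"
    d.mkdir(exist_ok=True)
    rows = []
    ratios = []
    for iid, s, arch in _iter_sections(config):
        pixels, inst, frame, _ = _load_section(out, iid, s)
        prof = radial.area_fraction_profile(inst, frame, config.n_bins_area)
        df = prof.to_frame()
        df.insert(0, "internode", iid)
        df.insert(1, "seed", s)
        rows.append(df)
        ratios.append(dict(internode=iid, seed=s,
                           area_ratio=radial.area_ratio(inst, frame)))
    pd.concat(rows, ignore_index=True).to_csv(
        d / "area_fraction_profiles.csv", index=False)
    pd.DataFrame(ratios).to_csv(d / "area_ratios.csv", index=False)

    bundles = pd.read_csv(out / "measurements" / "bundles.csv")
    moving = []
    for iid, grp in bundles.groupby("internode"):
        grp = grp.sort_values("relative_position")
        recs = [mm.BundleRecord(
            label=int(r.label), area_px=int(r.area_px),
            perimeter_px=r.perimeter_px, convex_area_px=r.convex_area_px,
            eccentricity=r.eccentricity, aspect=r.aspect, extent=r.extent,
            centroid=(r.centroid_row, r.centroid_col),
            bbox=(0, 0, 1, 1), touches_border=False,
            relative_position=r.relative_position,
        ) for r in grp.itertuples()]
        if len(recs) < config.moving_window:
            continue
        for desc in ("area_px", "eccentricity", "aspect", "extent"):
            mv = radial.moving_profile(recs, config.moving_window, desc)
            mv.insert(0, "internode", iid)
            mv.insert(1, "descriptor", desc)
            moving.append(mv)
    if moving:
        pd.concat(moving, ignore_index=True).to_csv(
            d / "moving_profiles.csv", index=False)
    return {"profiles": len(rows)}


def _stage_stats(config: RunConfig, out: Path) -> dict:
    d = out / "stats"
    d.mkdir(exist_ok=True)
    bundles = pd.read_csv(out / "measurements" / "bundles.csv")
    ratios = pd.read_csv(out / "profiles" / "area_ratios.csv") \
        if (out / "profiles" / "area_ratios.csv").exists() else None
    ids = [int(i) for i in sorted(bundles.internode.unique())]
    results = {}

    # per-bundle descriptors across internodes: rank-based (KW + DSCF)
    for desc in ("area_px", "eccentricity", "aspect", "relative_position"):
        groups = [bundles.loc[bundles.internode == i, desc].values for i in ids]
        H, p, pw = st.kruskal_dscf(groups, config.alpha)
        letters = st.compact_letters(pw, config.alpha)
        df = st.pairwise_to_frame(pw)
        df["group_a"] = [ids[i] for i in df.group_a]
        df["group_b"] = [ids[i] for i in df.group_b]
        df.to_csv(d / f"dscf_{desc}.csv", index=False)
        results[desc] = {"H": H, "p": p,
                         "letters": {ids[g]: l for g, l in letters.items()}}

    # per-section area ratios across internodes: ANOVA + Tukey
    if ratios is not None and ratios.groupby("internode").size().min() >= 2:
        groups = [ratios.loc[ratios.internode == i, "area_ratio"].values
                  for i in ids]
        F, p, pw = st.anova_tukey(groups, config.alpha)
        letters = st.compact_letters(pw, config.alpha)
        df = st.pairwise_to_frame(pw)
        df["group_a"] = [ids[i] for i in df.group_a]
        df["group_b"] = [ids[i] for i in df.group_b]
        df.to_csv(d / "tukey_area_ratio.csv", index=False)
        results["area_ratio"] = {"F": F, "p": p,
                                 "letters": {ids[g]: l for g, l in letters.items()}}
    (d / "summary.json").write_text(json.dumps(results, indent=1))
    return results


def _vae_training_images(config: RunConfig, out: Path) -> np.ndarray:
    imgs = []
    for iid, s, arch in _iter_sections(config):
        pixels, inst, frame, _ = _load_section(out, iid, s)
        recs = mm.measure_all(inst, frame)
        imgs.append(vm.extract_bundle_images(inst, recs, config.vae.input_size))
    return np.concatenate(imgs, axis=0)


def _stage_train_vae(config: RunConfig, out: Path) -> dict:
    images = _vae_training_images(config, out)
    model, hist = vm.train_vae(images, config.vae)
    vm.save_vae(model, str(out / "vae_model.npz"))
    pd.DataFrame(hist).to_csv(out / "vae_history.csv", index=False)
    return {"images": int(len(images)), "final_loss": float(hist["loss"][-1])}


def _stage_morph(config: RunConfig, out: Path) -> dict:
    model = vm.load_vae(str(out / "vae_model.npz"))
    iid = config.internodes[0]
    s = config.seeds[0]
    pixels, inst, frame, _ = _load_section(out, iid, s)
    recs = mm.measure_all(inst, frame)
    images = vm.extract_bundle_images(inst, recs, config.vae.input_size)
    anchors, positions = vm.select_anchors(recs, images, config.anchor_positions)
    # nearest-bundle positions can collide at the extremes; nudge duplicates
    uniq = []
    for p in positions:
        while any(abs(p - q) < 1e-9 for q in uniq):
            p += 1e-6
        uniq.append(p)
    path = vm.morph(model, anchors, uniq, config.frames_per_segment)
    d = out / "morph"
    d.mkdir(exist_ok=True)
    for i, frame_img in enumerate(path.frames):
        cio.save_image8(frame_img, d / f"frame_{i:04d}.png")
    pd.DataFrame(path.latents).to_csv(d / "latents.csv", index=False)
    return {"frames": int(len(path.frames))}


_STAGE_FNS = {
    "generate": _stage_generate,
    "train-seg": _stage_train_seg,
    "predict": _stage_predict,
    "measure": _stage_measure,
    "profile": _stage_profile,
    "stats": _stage_stats,
    "train-vae": _stage_train_vae,
    "morph": _stage_morph,
}
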