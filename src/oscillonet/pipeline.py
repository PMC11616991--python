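"""End-to-end pipeline driver.

Runs the stages in method order — spectra -> dominance -> network mapping ->
group statistics -> molecular correlation — on synthetic inputs generated
with known ground truth, and writes every artefact with a provenance
sidecar. The run is deterministic under the configured seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dominance as dom
from . import groupstats, io, molmap, netmap, synthetic
from .config import PipelineConfig
from .spectral import parameterize
from .volume import VolumeImage, mni_grid, write_nifti

logger = logging.getLogger("oscillonet.pipeline")

__all__ = ["run_pipeline", "demo_grid", "demo_parcellation"]


def demo_grid(voxel_mm: float = 4.0) -> VolumeImage:
    """Coarse MNI-like grid for synthetic end-to-end runs."""
    shape = tuple(int(round(s * 2.0 / voxel_mm)) for s in (91, 109, 91))
    return mni_grid(shape=shape, voxel_mm=voxel_mm)


def _community_map(grid: VolumeImage) -> VolumeImage:
    """Anterior and posterior 'networks' covering the cortical sampling box."""
    vals = np.zeros(grid.shape)
    idx = np.indices(grid.shape).reshape(3, -1).T
    mm = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    inside = (
        (np.abs(mm[:, 0]) <= 70)
        & (mm[:, 1] >= -100)
        & (mm[:, 1] <= 60)
        & (mm[:, 2] >= -45)
        & (mm[:, 2] <= 75)
    )
    label = np.where(mm[:, 1] < -20, 1, 2)
    flat = vals.ravel()
    flat[inside] = label[inside]
    return VolumeImage(flat.reshape(grid.shape), grid.affine.copy())


def _demo_coord_sampler(rng: np.random.Generator, band: str) -> np.ndarray:
    """Band-dependent topography: beta anterior, alpha/theta posterior,
    mirroring the observed anterior-posterior dominance gradient."""
    x = rng.uniform(15.0, 65.0) * rng.choice([-1.0, 1.0])
    if band == "beta":
        y = rng.uniform(-10.0, 55.0)
    elif band in ("alpha", "theta"):
        y = rng.uniform(-95.0, -30.0)
    else:
        y = rng.uniform(-95.0, 55.0)
    z = rng.uniform(-40.0, 70.0)
    return np.array([x, y, z])


def demo_parcellation(grid: VolumeImage, seed: int = 0) -> molmap.Parcellation:
    """Synthetic compound parcellation: block parcels tagged as cortex,
    basal ganglia, or cerebellum (stand-in for the real compound atlas)."""
    rng = np.random.default_rng(seed)
    idx = np.indices(grid.shape).reshape(3, -1).T
    mm = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]

    def blocks(box_lo, box_hi, n_split) -> np.ndarray:
        inside = np.all((mm >= box_lo) & (mm <= box_hi), axis=1)
        out = np.zeros(len(mm), dtype=int)
        # split the box into n_split^3-ish blocks along each axis
        edges = [
            np.linspace(box_lo[d], box_hi[d] + 1e-6, n_split[d] + 1) for d in range(3)
        ]
        code = np.zeros(len(mm), dtype=int)
        for d in range(3):
            code = code * n_split[d] + np.clip(
                np.searchsorted(edges[d], mm[:, d], side="right") - 1, 0, n_split[d] - 1
            )
        out[inside] = code[inside] + 1
        return out

    atlases = []
    specs = [
        ("bg", "basal_ganglia", (-30, -30, -20), (30, 20, 20), (3, 3, 2)),
        ("cb", "cerebellum", (-45, -100, -45), (45, -55, -5), (3, 2, 2)),
        ("ctx", "cortex", (-70, -100, -45), (70, 60, 75), (6, 7, 5)),
    ]
    for atlas_id, comp, lo, hi, nsp in specs:
        lab = blocks(np.array(lo, float), np.array(hi, float), nsp)
        img = VolumeImage(lab.reshape(grid.shape).astype(float), grid.affine.copy())
        names = {int(l): f"{atlas_id}_{int(l):03d}" for l in np.unique(lab) if l > 0}
        atlases.append((img, names, comp, atlas_id))
    return molmap.build_compound_parcellation(atlases, target_grid=grid)


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run the full synthetic pipeline; returns a result bundle.

    Keys: ``cohort``, ``models``, ``dominance`` (per-channel table),
    ``tabulation``, ``hemisphere_test``, ``functional_group`` /
    ``structural_group`` (per band), ``tmap``, ``report``.
    """
    seed = int(config.seed)
    out_dir = Path(config.output_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort spectra and parameterisation -------------------
    logger.info("stage spectra: generating and parameterising %d channels", config.n_channels)
    cohort = synthetic.gen_cohort(
        synthetic.CohortTruth(
            n_channels=config.n_channels,
            n_subjects=max(4, config.n_channels // 12),
            coord_sampler=_demo_coord_sampler,
        ),
        seed=seed,
    )
    freqs = np.arange(config.freq_lo_hz, config.freq_hi_hz + 1e-9, config.freq_step_hz)
    models = {}
    for cid, truth in cohort.spectrum_truths.items():
        try:
            models[cid] = parameterize(synthetic.gen_spectrum(truth, freqs), config.spectral)
        except ValueError as exc:
            raise RuntimeError(f"stage spectra failed at channel {cid}: {exc}") from exc

    # --- stage 2: dominance ---------------------------------------------
    bands = dom.default_bands(config.band_scheme)
    peaks = dom.peak_table(models, cohort.table, bands)
    peaks_z = dom.zscore_peak_heights(peaks)
    dominant = dom.classify_cohort(peaks_z, channel_ids=cohort.table["channel_id"])
    table = cohort.table.copy()
    table["dominant_band"] = table["channel_id"].map(dominant)
    table["hemisphere"] = table["x_mm"].map(dom.hemisphere_of)
    table["true_band"] = table["channel_id"].map(cohort.true_bands)
    tabulation = dom.tabulate_dominance(table, group_by="hemisphere")
    hemi = dom.hemisphere_test(table, "beta")

    # --- stage 3: network mapping ----------------------------------------
    grid = demo_grid()
    conn_grid = demo_grid(voxel_mm=8.0)
    community = _community_map(conn_grid)
    connectome = synthetic.gen_connectome(
        n_subjects=4,
        community_map=community,
        n_timepoints=60,
        noise=synthetic.noise_for_target_r(0.6),
        seed=seed + 1,
    )
    bundles = [
        np.column_stack([np.linspace(-70, 70, 60), np.full(60, -20.0), np.full(60, 20.0)]),
        np.column_stack([np.zeros(60), np.linspace(-95, 55, 60), np.full(60, 10.0)]),
    ]
    tractogram = synthetic.gen_tractogram(bundles, n_per_bundle=80, jitter_mm=2.0, seed=seed + 2)

    fmaps: dict[str, list[netmap.ConnectivityMap]] = {}
    smaps: dict[str, list[netmap.ConnectivityMap]] = {}
    for row in table.itertuples():
        band = row.dominant_band
        if band not in ("theta", "alpha", "beta", "gamma"):
            continue
        xyz = (row.x_mm, row.y_mm, row.z_mm)
        try:
            # 8 mm connectome grid: use the containing voxel as the seed so a
            # 5 mm sphere cannot fall between coarse voxel centers
            seed_img = netmap.make_seed_image(xyz, radius_mm=0.0, template_grid=conn_grid)
            fmap = netmap.functional_map(seed_img, connectome, seed_channel_id=row.channel_id)
            fmap = netmap.ConnectivityMap(
                image=netmap.smooth_volume(fmap.image, config.smooth_sd_mm),
                modality="functional",
                seed_channel_id=row.channel_id,
                group=band,
            )
            smap = netmap.structural_map(
                xyz, config.seed_radius_mm, tractogram, grid, seed_channel_id=row.channel_id
            )
        except ValueError as exc:
            raise RuntimeError(
                f"stage netmap failed at channel {row.channel_id}: {exc}"
            ) from exc
        fmaps.setdefault(band, []).append(fmap)
        smaps.setdefault(band, []).append(smap)

    functional_group = {
        b: netmap.group_aggregate(ms, "functional") for b, ms in fmaps.items() if len(ms) >= 2
    }
    structural_group = {b: netmap.group_aggregate(ms, "structural") for b, ms in smaps.items()}

    # --- stage 4: group statistics (beta vs alpha) ------------------------
    tmap = None
    if len(fmaps.get("beta", [])) >= 2 and len(fmaps.get("alpha", [])) >= 2:
        tmap = groupstats.voxelwise_ttest(fmaps["beta"], fmaps["alpha"])
        tmap = groupstats.fwe_threshold(
            tmap,
            fmaps["beta"],
            fmaps["alpha"],
            alpha=config.fwe_alpha,
            method=config.fwe_method,
            n_perm=min(config.fwe_n_perm, 500),
            seed=seed + 3,
        )

    # --- stage 5: molecular correlation -----------------------------------
    parc = demo_parcellation(conn_grid, seed=seed + 4)
    report = None
    if "beta" in functional_group:
        beta_profile = molmap.parcel_profile(functional_group["beta"], parc)
        ref = np.nan_to_num(beta_profile.values, nan=0.0)
        ref = ref + 1e-9 * np.arange(len(ref))  # break exact ties from empty parcels
        pet = synthetic.gen_pet(parc, ref, target_rho=0.5, seed=seed + 5)
        report = molmap.compartment_report(
            {"beta_functional": functional_group["beta"]},
            {"dopamine_aggregate": pet},
            parc,
            n_perm=min(config.corr_n_perm, 2000),
            seed=seed + 6,
        )

    # --- outputs ----------------------------------------------------------
    if write:
        io.write_channel_table(table, out_dir / "dominance.tsv")
        tabulation.to_csv(out_dir / "tabulation_hemisphere.csv", index=False)
        if tmap is not None:
            write_nifti(tmap.t, out_dir / "tmap_beta_gt_alpha.nii")
            write_nifti(tmap.sig_a_gt_b, out_dir / "sig_beta_gt_alpha.nii")
        if report is not None:
            report.to_csv(out_dir / "correlation_report.csv", index=False)
        for band, img in structural_group.items():
            write_nifti(img, out_dir / f"structural_group_{band}.nii")
        cfg = config.to_dict()
        thr = dict(tmap.threshold) if tmap is not None else {}
        thr.pop("null_max", None)
        io.write_provenance(
            out_dir / "provenance.json",
            cfg,
            seeds={"root": seed, "fwe": seed + 3, "pet": seed + 5, "corr": seed + 6},
        )

    return {
        "cohort": cohort,
        "models": models,
        "dominance": table,
        "tabulation": tabulation,
        "hemisphere_test": hemi,
        "functional_group": functional_group,
        "structural_group": structural_group,
        "tmap": tmap,
        "report": report,
    }
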