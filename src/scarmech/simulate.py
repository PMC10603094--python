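"""Seeded synthetic-data generators for every pipeline input modality.

Each generator emulates the statistical structure of one measurement arm —
LFQ proteomics tables, two-region Brillouin/refractive-index scenes,
polarized OCT stacks, AFM approach force curves, per-animal group tables and
qRT-PCR Ct tables — with the ground truth returned alongside so every
downstream stage can be tested closed-loop, with no external data.

All generators draw from an independent RNG stream derived from the master
seed by stable sub-seeding (``SeedSequence(seed, spawn_key=(index,))``), so
adding a generator never perturbs the output of the others, and the same
``SimulationSpec`` always yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import ForceCurve, hertz_force, kvm_force
from .brillouin import BrillouinMap, RefractiveField
from .optical import PolarizedStack
from .proteomics import AbundanceMatrix

__all__ = ["SimulationSpec", "generate_lfq_table", "generate_brillouin_scene",
           "generate_cpoct_stack", "generate_force_curve",
           "generate_group_table", "generate_ct_table", "write_scene"]

# stable RNG stream index per generator
_STREAM = {"lfq": 0, "brillouin": 1, "cpoct": 2, "afm": 3, "group": 4, "ct": 5}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults mirror the measured study conditions: 3 biological replicates
    per proteomics condition with roughly a fifth of the detected inventory
    regulated after injury; 0.5 um Brillouin pixels with lesion/background
    shifts near 5.3/5.4 GHz; co-polarization ratios around 0.71-0.75; and an
    AFM probe of 18.5 um bead radius indenting at 7 um/s to a 12 nN setpoint
    on ~500 Pa tissue.
    """

    seed: int = 0
    # proteomics
    n_proteins: int = 4782
    n_replicates_per_condition: int = 3
    frac_regulated: float = 0.19
    effect_log2fc: float = 1.0
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.5
    replicate_log2_sd: float = 0.25
    missingness_shift: float = 1.8     # sd units below the sample mean
    missingness_width: float = 0.3     # sd units, logistic transition width
    frac_flagged: float = 0.01         # decoy/contaminant rows among nulls
    # imaging geometry
    map_shape: tuple[int, int] = (48, 96)   # rows x cols
    pixel_size_um: float = 0.5
    lesion_extent_um: tuple[float, float] = (40.0, 20.0)  # width x height
    # Brillouin / RI scene
    brillouin_lesion_ghz: float = 5.324
    brillouin_background_ghz: float = 5.40
    brillouin_noise_sd_ghz: float = 0.02
    ri_lesion: float = 1.3636
    ri_background: float = 1.3680
    ri_noise_sd: float = 0.001
    # CP-OCT
    cpoct_n_slices: int = 8
    cpoct_delta_lesion: float = 0.750
    cpoct_delta_background: float = 0.709
    cpoct_amplitude_mean: float = 100.0
    cpoct_noise_sd: float = 2.0
    # AFM forward truth
    afm_e_true_pa: float = 500.0
    afm_eta_true_pa_s: float = 5.0
    afm_contact_point_um: float = 2.0
    afm_force_noise_n: float = 0.1e-9
    afm_n_points: int = 500
    afm_speed_m_per_s: float = 7e-6
    afm_setpoint_n: float = 12e-9
    afm_bead_radius_m: float = 18.5e-6
    afm_poisson: float = 0.5
    # group / Ct tables
    group_n_per_group: int = 12
    group_control_mean: float = 1.0
    group_shift: float = 0.0
    group_sd: float = 0.2
    group_distribution: str = "normal"     # "normal" | "lognormal"
    ct_target_ctrl: float = 22.0
    ct_target_cond: float = 20.0
    ct_ref_ctrl: float = 15.0
    ct_ref_cond: float = 15.0
    ct_replicate_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_replicates_per_condition",
                     "cpoct_n_slices", "afm_n_points", "group_n_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ValueError("frac_regulated must be in [0, 1]")
        if self.afm_e_true_pa <= 0 or self.afm_eta_true_pa_s < 0:
            raise ValueError("AFM truth requires E > 0 and eta >= 0")
        if self.afm_speed_m_per_s <= 0:
            raise ValueError("approach speed must be positive")
        if self.cpoct_amplitude_mean < 0:
            raise ValueError("amplitude must be non-negative")
        if not (0.0 <= self.cpoct_delta_lesion <= 1.0
                and 0.0 <= self.cpoct_delta_background <= 1.0):
            raise ValueError("co-polarization ratios must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAM[stream],)))


def generate_lfq_table(spec: SimulationSpec):
    """Synthetic proteinGroups-style abundance matrix with known truth.

    Baseline per-protein log2 intensities are normal across proteins with
    tight replicate noise; a seeded subset (``frac_regulated``, split evenly
    up/down) is shifted by +/- ``effect_log2fc`` in the lesioned condition.
    Low-abundance values drop out at random with probability following a
    logistic curve centred ``missingness_shift`` sample SDs below the sample
    mean (missing-not-at-random), and a small fraction of null rows carries a
    decoy or contaminant flag.

    Returns ``(AbundanceMatrix, truth)`` where ``truth`` is a per-protein
    Series with values ``up`` / ``down`` / ``null``.
    """
    rng = spec.rng("lfq")
    n, reps = spec.n_proteins, spec.n_replicates_per_condition
    ids = [f"P{i:05d}" for i in range(n)]
    samples = [f"ctrl_{r+1}" for r in range(reps)] + [f"les_{r+1}" for r in range(reps)]
    conditions = pd.Series({s: ("control" if s.startswith("ctrl") else "lesioned")
                            for s in samples})

    base = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=n)
    x = base[:, None] + rng.normal(0.0, spec.replicate_log2_sd, size=(n, 2 * reps))

    n_reg = int(round(spec.frac_regulated * n))
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    n_up = (n_reg + 1) // 2
    up_idx, down_idx = reg_idx[:n_up], reg_idx[n_up:]
    x[up_idx, reps:] += spec.effect_log2fc
    x[down_idx, reps:] -= spec.effect_log2fc
    truth = pd.Series("null", index=ids, name="truth")
    truth.iloc[up_idx] = "up"
    truth.iloc[down_idx] = "down"

    # MNAR dropout: logistic in distance below the per-sample mean
    for j in range(2 * reps):
        col = x[:, j]
        thr = col.mean() - spec.missingness_shift * col.std(ddof=1)
        scale = max(spec.missingness_width * col.std(ddof=1), 1e-12)
        p_drop = 1.0 / (1.0 + np.exp((col - thr) / scale))
        col[rng.random(n) < p_drop] = np.nan

    flags = pd.DataFrame(False, index=ids,
                         columns=["reverse", "contaminant", "identified_by_site"])
    null_idx = np.setdiff1d(np.arange(n), reg_idx)
    n_flag = int(round(spec.frac_flagged * n))
    if n_flag and len(null_idx):
        flagged = rng.choice(null_idx, size=min(n_flag, len(null_idx)), replace=False)
        kinds = rng.integers(0, 3, size=len(flagged))
        for i, k in zip(flagged, kinds):
            flags.iloc[i, int(k)] = True

    m = AbundanceMatrix(
        intensities=pd.DataFrame(x, index=ids, columns=samples),
        conditions=conditions,
        gene_symbols=pd.Series([f"gene{i}" for i in range(n)], index=ids),
        flags=flags,
    )
    return m, truth


def _lesion_mask(spec: SimulationSpec) -> np.ndarray:
    rows, cols = spec.map_shape
    w_px = int(round(spec.lesion_extent_um[0] / spec.pixel_size_um))
    h_px = int(round(spec.lesion_extent_um[1] / spec.pixel_size_um))
    if w_px > cols or h_px > rows:
        raise ValueError(
            f"lesion ROI {w_px}x{h_px} px exceeds map {rows}x{cols} px")
    r0 = (rows - h_px) // 2
    c0 = (cols - w_px) // 2
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0:r0 + h_px, c0:c0 + w_px] = True
    return mask


def generate_brillouin_scene(spec: SimulationSpec):
    """Two-region Brillouin map plus co-registered refractive-index field.

    A rectangular lesion of ``lesion_extent_um`` sits centred in a background
    region; both carry independent Gaussian pixel noise.  Returns
    ``(BrillouinMap, RefractiveField, truth)`` with the region-true means and
    the lesion mask recorded in ``truth``.
    """
    rng = spec.rng("brillouin")
    mask = _lesion_mask(spec)
    shift = np.where(mask, spec.brillouin_lesion_ghz, spec.brillouin_background_ghz)
    shift = shift + rng.normal(0.0, spec.brillouin_noise_sd_ghz, size=mask.shape)
    ri = np.where(mask, spec.ri_lesion, spec.ri_background)
    ri = ri + rng.normal(0.0, spec.ri_noise_sd, size=mask.shape)
    truth = {
        "lesion_mask": mask,
        "brillouin_lesion_ghz": spec.brillouin_lesion_ghz,
        "brillouin_background_ghz": spec.brillouin_background_ghz,
        "ri_lesion": spec.ri_lesion,
        "ri_background": spec.ri_background,
    }
    return (BrillouinMap(shift, pixel_size_um=spec.pixel_size_um),
            RefractiveField(ri, pixel_size_um=spec.pixel_size_um),
            truth)


def generate_cpoct_stack(spec: SimulationSpec):
    """Co-/cross-polarized amplitude stacks with known per-region delta.

    The total backscattered amplitude is an exponential (speckle-like) field
    around ``cpoct_amplitude_mean``; the co-polarized fraction is the
    region-true delta (lesion rectangle vs background), with additive
    Gaussian amplitude noise clipped at zero.  Returns
    ``(PolarizedStack, truth)``.
    """
    rng = spec.rng("cpoct")
    mask = _lesion_mask(spec)
    delta = np.where(mask, spec.cpoct_delta_lesion, spec.cpoct_delta_background)
    shape = (spec.cpoct_n_slices,) + spec.map_shape
    a_tot = rng.exponential(spec.cpoct_amplitude_mean, size=shape)
    a_co = delta[None] * a_tot
    a_cross = (1.0 - delta[None]) * a_tot
    if spec.cpoct_noise_sd > 0:
        a_co = np.clip(a_co + rng.normal(0, spec.cpoct_noise_sd, shape), 0, None)
        a_cross = np.clip(a_cross + rng.normal(0, spec.cpoct_noise_sd, shape), 0, None)
    truth = {"lesion_mask": mask,
             "delta_lesion": spec.cpoct_delta_lesion,
             "delta_background": spec.cpoct_delta_background}
    return PolarizedStack(a_co, a_cross, pixel_size_um=spec.pixel_size_um), truth


def _max_depth_for_setpoint(spec: SimulationSpec) -> float:
    """Indentation depth at which the forward model reaches the setpoint force."""
    lo, hi = 0.0, 20e-6
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = (kvm_force(mid, spec.afm_e_true_pa, spec.afm_eta_true_pa_s,
                       spec.afm_speed_m_per_s, spec.afm_bead_radius_m,
                       spec.afm_poisson)
             if spec.afm_eta_true_pa_s > 0 else
             hertz_force(mid, spec.afm_e_true_pa, spec.afm_bead_radius_m,
                         spec.afm_poisson))
        if f < spec.afm_setpoint_n:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_force_curve(spec: SimulationSpec) -> ForceCurve:
    """Constant-speed approach force curve from the chosen forward model.

    Hertz-elastic when ``afm_eta_true_pa_s`` is 0, else the Kelvin-Voigt-
    Maxwell solution — the same forward models the fitting stage inverts.
    The probe travels at constant speed from zero through the contact point
    at ``afm_contact_point_um`` until the setpoint force is reached, sampled
    at ``afm_n_points`` with additive Gaussian force noise.  The generating
    parameters are recorded in ``curve.truth``.
    """
    rng = spec.rng("afm")
    contact = spec.afm_contact_point_um * 1e-6
    depth = _max_depth_for_setpoint(spec)
    x = np.linspace(0.0, contact + depth, spec.afm_n_points)
    t = x / spec.afm_speed_m_per_s
    delta = np.clip(x - contact, 0.0, None)
    if spec.afm_eta_true_pa_s > 0:
        force = kvm_force(delta, spec.afm_e_true_pa, spec.afm_eta_true_pa_s,
                          spec.afm_speed_m_per_s, spec.afm_bead_radius_m,
                          spec.afm_poisson)
    else:
        force = hertz_force(delta, spec.afm_e_true_pa, spec.afm_bead_radius_m,
                            spec.afm_poisson)
    if spec.afm_force_noise_n > 0:
        force = force + rng.normal(0.0, spec.afm_force_noise_n, size=force.shape)
    return ForceCurve(
        time_s=t, indentation_m=x, force_n=force,
        bead_radius_m=spec.afm_bead_radius_m, poisson=spec.afm_poisson,
        approach_speed_m_per_s=spec.afm_speed_m_per_s,
        setpoint_n=spec.afm_setpoint_n,
        truth={"E_pa": spec.afm_e_true_pa, "eta_pa_s": spec.afm_eta_true_pa_s,
               "contact_point_m": contact},
    )


def generate_group_table(spec: SimulationSpec) -> pd.DataFrame:
    """Per-animal two-group measurement table with a specified group shift.

    ``group_distribution="normal"`` draws N(mean, sd); ``"lognormal"`` draws
    a right-skewed sample with matching mean, which a Shapiro-Wilk gate
    should reject for moderately large n.  Returns a DataFrame with columns
    ``value``, ``condition`` and ``animal``.
    """
    if spec.group_n_per_group < 2:
        raise ValueError("need n >= 2 animals per group")
    rng = spec.rng("group")
    n = spec.group_n_per_group
    means = {"control": spec.group_control_mean,
             "treated": spec.group_control_mean + spec.group_shift}
    rows = []
    for cond, mu in means.items():
        if spec.group_distribution == "normal":
            vals = rng.normal(mu, spec.group_sd, size=n)
        elif spec.group_distribution == "lognormal":
            # lognormal with sigma from the CV of the requested noise
            cv = spec.group_sd / abs(mu) if mu else spec.group_sd
            sigma = np.sqrt(np.log1p(cv ** 2))
            vals = mu * rng.lognormal(-sigma ** 2 / 2, sigma, size=n)
        else:
            raise ValueError(f"unknown distribution {spec.group_distribution!r}")
        rows.extend({"value": v, "condition": cond, "animal": f"{cond}_{i+1}"}
                    for i, v in enumerate(vals))
    return pd.DataFrame(rows)


def generate_ct_table(spec: SimulationSpec) -> pd.DataFrame:
    """qRT-PCR Ct table (target + reference gene, control vs condition).

    The delta-delta-Ct truth follows directly from the four specified mean Ct
    values; replicate noise is Gaussian with ``ct_replicate_sd``.
    """
    rng = spec.rng("ct")
    rows = []
    for gene, cond, mu in (("target", "control", spec.ct_target_ctrl),
                           ("target", "condition", spec.ct_target_cond),
                           ("reference", "control", spec.ct_ref_ctrl),
                           ("reference", "condition", spec.ct_ref_cond)):
        for r in range(3):
            ct = mu + (rng.normal(0, spec.ct_replicate_sd)
                       if spec.ct_replicate_sd > 0 else 0.0)
            rows.append({"gene": gene, "condition": cond, "replicate": r + 1,
                         "ct": ct})
    df = pd.DataFrame(rows)
    ddct = (spec.ct_target_cond - spec.ct_ref_cond) \
        - (spec.ct_target_ctrl - spec.ct_ref_ctrl)
    df.attrs["truth_fc"] = 2.0 ** (-ddct)
    return df


def write_scene(outdir, spec: SimulationSpec, *, modality: str) -> list[Path]:
    """Write one modality's synthetic data plus a JSON ground-truth sidecar.

    ``modality`` is one of lfq / brillouin / cpoct / afm / group / ct.
    Returns the written paths.
    """
    import tifffile

    from .proteomics import write_protein_groups

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def sidecar(name: str, payload: dict) -> None:
        p = outdir / f"{name}_truth.json"
        p.write_text(json.dumps(payload, indent=2, default=str))
        written.append(p)

    if modality == "lfq":
        m, truth = generate_lfq_table(spec)
        p = outdir / "protein_groups.tsv"
        write_protein_groups(m, p)
        written.append(p)
        sidecar("lfq", {"truth": truth.to_dict(),
                        "conditions": m.conditions.to_dict()})
    elif modality == "brillouin":
        bmap, rfield, truth = generate_brillouin_scene(spec)
        for name, arr in (("brillouin_ghz", bmap.data), ("ri", rfield.data)):
            p = outdir / f"{name}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
            written.append(p)
        sidecar("brillouin", {k: v for k, v in truth.items() if k != "lesion_mask"}
                | {"pixel_size_um": spec.pixel_size_um})
    elif modality == "cpoct":
        stack, truth = generate_cpoct_stack(spec)
        for name, arr in (("a_co", stack.a_co), ("a_cross", stack.a_cross)):
            p = outdir / f"{name}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
            written.append(p)
        sidecar("cpoct", {k: v for k, v in truth.items() if k != "lesion_mask"})
    elif modality == "afm":
        curve = generate_force_curve(spec)
        p = outdir / "force_curve.tsv"
        curve.to_tsv(p)
        written.append(p)
        sidecar("afm", curve.truth)
    elif modality == "group":
        df = generate_group_table(spec)
        p = outdir / "group_table.csv"
        df.to_csv(p, index=False)
        written.append(p)
        sidecar("group", {"shift": spec.group_shift})
    elif modality == "ct":
        df = generate_ct_table(spec)
        p = outdir / "ct_table.csv"
        df.to_csv(p, index=False)
        written.append(p)
        sidecar("ct", {"truth_fc": df.attrs["truth_fc"]})
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return written
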