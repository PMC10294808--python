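"""End-to-end study protocols.

Each function reproduces one complete measurement chain at desk scale:
generate (or build) the inputs, run the method, and report the measured
quantities.  The test-suite and the reproduction script both call these,
so the numbers they check are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import analysis as an
from . import mc
from . import sorption
from . import synthetic as syn
from .structure import (
    UnitCell,
    build_pyroaurite,
    build_slab,
    build_supercell,
    surface_hydroxyl_indices,
)

__all__ = [
    "freundlich_recovery",
    "sips_recovery",
    "kp_recovery",
    "slab_protocol",
    "interlayer_exclusion",
    "build_study_slab",
]


def freundlich_recovery(which: str = "powder", seed: int = 0, n_points: int = 30,
                        sigma: float = 0.02) -> dict:
    """Generate a dye isotherm from the study's fitted Freundlich pair
    (powder or monolith), 30 log-spaced points over 120-3500 ppm with 2%
    multiplicative noise, and refit it.  Returns truth, estimates and SEs."""
    truth = syn.STUDY[f"{which}_freundlich"]
    d = syn.gen_isotherm_dataset(
        "freundlich", truth, n_points=n_points, noise=syn.NoiseModel(sigma=sigma, seed=seed)
    )
    fit = sorption.fit_freundlich(d)
    return {
        "truth": dict(truth),
        "k": fit.params["k"],
        "n": fit.params["n"],
        "se_k": fit.se["k"],
        "se_n": fit.se["n"],
        "r2": fit.r2,
    }


def sips_recovery(seed: int = 0, sigma: float = 0.02) -> dict:
    """Tetracycline-like S-shaped isotherm: 8 points over 5-40 g/L from the
    study's Sips parameters (no plateau in-window), refit with multi-start."""
    truth = syn.STUDY["tc_sips"]
    d = syn.gen_isotherm_dataset(
        "sips", truth, c_range=(5.0, 40.0), n_points=8,
        noise=syn.NoiseModel(sigma=sigma, seed=seed),
    )
    fit = sorption.fit_sips(d)
    return {
        "truth": dict(truth),
        "m": fit.params["m"],
        "se_m": fit.se["m"],
        "cooperative": fit.flags["cooperative"],
        "plateau": fit.flags["plateau"],
        "r2": fit.r2,
    }


def kp_recovery(seed: int = 0, sigma: float = 0.02) -> dict:
    """Monolith release curve from the study's Korsmeyer-Peppas exponent
    (k chosen so the 3 h maximum stays below 60% release); refit below the
    60% validity cap and rank all five release laws."""
    truth = syn.STUDY["monolith_release_kp"]
    d = syn.gen_release_dataset(truth, noise=syn.NoiseModel(sigma=sigma, seed=seed))
    fits = [sorption.fit_release(d, m) for m in sorption.RELEASE_MODELS]
    ranked = sorption.compare_models(fits)
    kp = next(f for f in fits if f.model == "korsmeyer_peppas")
    return {
        "truth": dict(truth),
        "n": kp.params["n"],
        "se_n": kp.se["n"],
        "k": kp.params["k"],
        "r2": kp.r2,
        "ranking": [f.model for f in ranked],
        "best": ranked[0].model,
    }


def build_study_slab(seed: int = 0, c: float = 23.41):
    """The study's surface model: a 3x3x2 supercell of the x=1/4,
    4.5-water cell (a=12.4 A), opened into a slab with a 30 A vacuum."""
    cell = UnitCell.hexagonal(12.4, c)
    fw = build_pyroaurite(0.25, 4.5, cell, seed=seed)
    sc = build_supercell(fw, (3, 3, 2))
    return build_slab(sc, vacuum=30.0)


def slab_protocol(seed: int = 0, params: mc.MCParams | None = None) -> dict:
    """Tetracycline on the carbonate-bearing external surface.

    Builds the study slab, makes the face carbonates mobile, places one TC
    molecule over the surface and runs the scaled-down Metropolis protocol
    (1e5 + 1e5 steps at 300 K unless overridden).  From the production
    frames it reports:

    * ``max_hbond``/``min_hbond``: the distance range of the TC-surface
      hydrogen bonds (H...A <= 3.0 A, angle >= 120 deg, both donor
      directions) detected in the lowest-energy sampled configuration —
      the converged-snapshot bond lengths that such simulations report;
    * ``min_contact``: the minimum over frames and carbonates of the
      nearest carbonate-to-surface-hydroxyl contact — the lower end of the
      carbonate-surface interaction-distance range.
    """
    slab = build_study_slab(seed=seed)
    tc = syn.get_fixture("tetracycline").as_guest()
    system = mc.slab_adsorption_system(slab, adsorbates=[tc], seed=seed + 1)
    params = params or mc.MCParams.scaled_down(seed=seed + 2)
    traj = mc.run_simulation(system, params)

    sfw = system.framework
    surf = surface_hydroxyl_indices(sfw, "bottom")
    els_fw = sfw.elements
    tc_gi = next(i for i, g in enumerate(system.guests) if g.name == "tetracycline")
    carb_ids = [i for i, g in enumerate(system.guests) if g.name == "carbonate"]
    gmap = traj.guest_molecule_map()
    per_mol = {i: gmap[i] for i in carb_ids}

    surf_o = [i for i in surf if els_fw[i] == "O"]
    bonds_per_frame = []
    frames = []
    for frame in traj.frames(extra_groups={"surface_oh": surf}):
        frames.append(frame)
        span = frame.select(f"guest_{tc_gi}")
        els = frame.elements
        tc_don = []
        for i in span:
            if els[i] not in ("O", "N"):
                continue
            for j in span:
                if els[j] == "H" and np.linalg.norm(frame.coords[j] - frame.coords[i]) < 1.25:
                    tc_don.append(i)
                    break
        tc_acc = [i for i in span if els[i] in ("O", "N")]
        bonds = an.find_hbonds(frame, tc_don, surf_o) + an.find_hbonds(frame, surf_o, tc_acc)
        bonds_per_frame.append([b.distance for b in bonds])

    # converged-snapshot bond lengths: rank frames by the adsorbate's own
    # interaction energy (LJ + screened Coulomb against framework and
    # co-adsorbed species) and read the bonds of its most strongly bound
    # configuration
    tc_energy = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        xyz = system.guest_coords(tc_gi, traj.centers[i], traj.quats[i])
        lj, real = system.guest_pair_energies(tc_gi, xyz, traj.centers[i], traj.quats[i])
        tc_energy[i] = lj.sum() + real.sum()
    order = np.argsort(tc_energy)
    best_bonds: list = []
    best_frame = int(order[0])
    for idx in order:
        if bonds_per_frame[int(idx)]:
            best_bonds = bonds_per_frame[int(idx)]
            best_frame = int(idx)
            break

    mn, mx, _hist, records = an.distance_range_summary(
        frames, "guest:carbonate", "surface_oh", cutoff=6.0, per_molecule=per_mol
    )
    return {
        "max_hbond": float(np.max(best_bonds)) if best_bonds else float("nan"),
        "min_hbond": float(np.min(best_bonds)) if best_bonds else float("nan"),
        "hbond_frame": best_frame,
        "frames_with_hbond": sum(1 for b in bonds_per_frame if b),
        "n_frames": traj.n_frames,
        "min_contact": mn,
        "max_contact": mx,
        "n_contacts": len(records),
        "acceptance": traj.acceptance,
        "trajectory": traj,
        "system": system,
    }


def interlayer_exclusion(seed: int = 0) -> dict:
    """Rigid-insertion scan of tetracycline into the carbonate-filled
    gallery at the experimental interlayer spacing (c = 23.4 A), against a
    ghost probe control."""
    cell = UnitCell.hexagonal(12.4, 23.4)
    fw = build_pyroaurite(0.25, 4.5, cell, seed=seed)
    sc = build_supercell(fw, (3, 3, 2))
    tc = syn.get_fixture("tetracycline").as_guest()
    ghost = syn.get_fixture("ghost").as_guest()
    scan_tc = mc.interlayer_insertion_scan(sc, tc, grid_spacing=4.0, n_orientations=6, seed=seed)
    scan_ghost = mc.interlayer_insertion_scan(sc, ghost, grid_spacing=4.0, n_orientations=1, seed=seed)
    return {
        "tc_min_energy": scan_tc.min_energy,
        "tc_feasible": scan_tc.feasible,
        "ghost_min_energy": scan_ghost.min_energy,
        "ghost_feasible": scan_ghost.feasible,
        "threshold": scan_tc.threshold,
    }
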