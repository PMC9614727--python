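import numpy as np
import pytest

from poreflux import (
    Frame,
    Selection,
    SyntheticSpec,
    Trajectory,
    axial_density,
    backbone_rmsd,
    chain_elongation,
    gen_density_system,
    gen_lipid_trajectory,
    radial_thickness,
)
from poreflux.exceptions import DomainError
from poreflux.profiles import kabsch_superpose

from conftest import make_traj


def binned_thickness_truth(info, bins):
    """Generator-side oracle: the imposed law averaged over each bin's own
    lipids, per leaflet (NaN where a leaflet has no lipid in the bin)."""
    law, rho, leaf = info["thickness_law"], info["rho"], info["leaflet"]
    nb = len(bins) - 1
    out = np.full(nb, np.nan)
    which = np.digitize(rho, bins) - 1
    for b in range(nb):
        up = (which == b) & (leaf == 1)
        lo = (which == b) & (leaf == -1)
        if up.any() and lo.any():
            out[b] = 0.5 * law(rho[up]).mean() + 0.5 * law(rho[lo]).mean()
    return out


def flat_bilayer_traj(geom, n_per_leaflet=60, n_frames=10, h=2.5, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rho = rng.uniform(0.3, 4.0, 2 * n_per_leaflet)
    theta = rng.uniform(0, 2 * np.pi, 2 * n_per_leaflet)
    sign = np.repeat([1.0, -1.0], n_per_leaflet)
    pos = np.empty((n_frames, 2 * n_per_leaflet, 3))
    for t in range(n_frames):
        pos[t, :, 0] = geom.origin[0] + rho * np.cos(theta)
        pos[t, :, 1] = geom.origin[1] + rho * np.sin(theta)
        pos[t, :, 2] = geom.origin[2] + sign * h / 2 + rng.normal(0, jitter, rho.size)
    traj = Trajectory(np.arange(n_frames) * 0.01, pos, np.array([10.0, 10.0, 12.0]))
    upper = Selection("u", np.arange(n_per_leaflet), "lipid-C2")
    lower = Selection("l", n_per_leaflet + np.arange(n_per_leaflet), "lipid-C2")
    return traj, upper, lower


class TestRadialThickness:
    def test_flat_bilayer_is_h_bio_everywhere(self, geom):
        traj, upper, lower = flat_bilayer_traj(geom, h=2.5)
        prof = radial_thickness(traj, upper, lower, geom)
        assert prof.occupied.any()
        np.testing.assert_allclose(
            prof.thickness[prof.occupied], 2.5, atol=1e-12
        )

    def test_single_lipid_per_leaflet_exact(self, geom):
        pos = np.array([[[6.0, 5.0, 7.3], [6.0, 5.0, 4.9]]])
        traj = Trajectory(np.zeros(1), pos, np.array([10.0, 10.0, 12.0]))
        upper = Selection("u", np.array([0]), "lipid-C2")
        lower = Selection("l", np.array([1]), "lipid-C2")
        prof = radial_thickness(
            traj, upper, lower, geom, bins=np.array([0.75, 1.25])
        )
        assert prof.z_upper[0] == pytest.approx(1.3)
        assert prof.z_lower[0] == pytest.approx(-1.1)
        assert prof.thickness[0] == pytest.approx(2.4)

    def test_recovers_imposed_quadratic_law(self, geom):
        spec = SyntheticSpec(seed=5)
        traj, info = gen_lipid_trajectory(spec, n_frames=40)
        bins = np.arange(0.5, 4.25, 0.25)
        prof = radial_thickness(traj, info["c2_upper"], info["c2_lower"], geom, bins)
        h_true = binned_thickness_truth(info, bins)
        occ = prof.occupied & np.isfinite(h_true)
        assert occ.sum() >= 10
        z = np.abs(prof.thickness[occ] - h_true[occ]) / np.maximum(
            prof.se[occ], 1e-12
        )
        # unbiased recovery at the 2-SE scale: the RMS z-score over bins
        # must sit at the few-percent level a calibrated SE implies (E[z^2]
        # = 1); a systematic bias of even half an SE per bin would fail
        assert np.sqrt(np.mean(z**2)) <= 2.0
        assert z.max() <= 5.0

    def test_invariant_under_axial_translation_with_recentering(self, geom):
        traj, upper, lower = flat_bilayer_traj(geom, h=2.5, jitter=0.02)
        both = Selection(
            "all", np.concatenate([upper.indices, lower.indices]), "protein-backbone"
        )
        shifted = Trajectory(
            traj.times, traj.positions + np.array([0, 0, 1.7]), traj.box
        )
        p0 = radial_thickness(traj, upper, lower, geom, center_sel=both)
        p1 = radial_thickness(shifted, upper, lower, geom, center_sel=both)
        np.testing.assert_allclose(
            p1.thickness[p1.occupied], p0.thickness[p0.occupied], atol=1e-9
        )

    def test_empty_selection_rejected(self, geom):
        traj, upper, lower = flat_bilayer_traj(geom)
        empty = Selection("e", np.array([], dtype=int), "lipid-C2")
        with pytest.raises(DomainError):
            radial_thickness(traj, empty, lower, geom)


class TestAxialDensity:
    def test_uniform_gas_matches_NV(self, geom):
        rng = np.random.default_rng(4)
        N, frames = 400, 30
        box = np.array([10.0, 10.0, 12.0])
        pos = rng.uniform(0, 1, (frames, N, 3)) * box
        traj = Trajectory(np.arange(frames) * 0.01, pos, box)
        sel = Selection("w", np.arange(N), "water-oxygen")
        # bins are in axial coordinates about the channel origin
        prof = axial_density(
            traj, sel, geom, np.arange(-6.0, 6.1, 0.5), area=100.0
        )
        target = N / (100.0 * 12.0)
        counting = np.sqrt(target / (100.0 * 0.5 * frames))
        assert np.all(np.abs(prof.density - target) < 5 * counting)

    def test_density_conservation_identity(self, geom):
        rng = np.random.default_rng(8)
        box = np.array([10.0, 10.0, 12.0])
        pos = rng.uniform(0, 1, (10, 50, 3)) * box
        traj = Trajectory(np.arange(10) * 0.01, pos, box)
        sel = Selection("w", np.arange(50), "water-oxygen")
        bins = np.arange(-6.0, 6.1, 0.4)
        prof = axial_density(traj, sel, geom, bins, area=100.0)
        total = np.sum(prof.density * 100.0 * np.diff(bins))
        assert total == pytest.approx(prof.mean_count, rel=1e-12)

    def test_exclusion_zone_density_is_zero(self, geom):
        spec = SyntheticSpec(seed=6)
        traj, waters, ions, truth = gen_density_system(spec, n_frames=20)
        bins = np.arange(-6.0, 6.01, 0.25)
        prof = axial_density(traj, waters, geom, bins, area=truth["area"])
        centers = prof.bin_centers
        inner = np.abs(centers) <= spec.z_excl - 0.125
        assert np.all(prof.density[inner] == 0.0)

    def test_empty_selection_zero_profile(self, geom):
        traj = make_traj(np.full(5, 6.0))
        empty = Selection("e", np.array([], dtype=int), "ion")
        prof = axial_density(traj, empty, geom, np.arange(-2, 2.1, 0.5), area=10.0)
        assert not prof.density.any()

    def test_zero_bin_width_rejected(self, geom):
        traj = make_traj(np.full(5, 6.0))
        sel = Selection("w", np.array([0]), "water-oxygen")
        with pytest.raises(DomainError):
            axial_density(traj, sel, geom, np.array([0.0, 0.0, 1.0]), area=10.0)


class TestChainElongation:
    def straight_chain_traj(self, geom, angle="z", L=1.2, nc=8):
        # one lipid: C2 at rho=2, two identical chains
        frac = np.linspace(0, 1, nc)
        if angle == "z":
            chain = np.column_stack(
                [np.full(nc, 7.0), np.full(nc, 5.0), 7.25 - L * frac]
            )
        else:  # lying in the xy-plane
            chain = np.column_stack(
                [7.0 + L * frac, np.full(nc, 5.0), np.full(nc, 7.25)]
            )
        c2 = np.array([[7.0, 5.0, 7.25]])
        pos = np.vstack([c2, chain, chain + np.array([0.05, 0, 0])])[None]
        traj = Trajectory(np.zeros(1), pos, np.array([10.0, 10.0, 12.0]))
        tails = [(0, 1 + np.arange(nc), 1 + nc + np.arange(nc))]
        return traj, tails

    def test_all_trans_z_chain_elongation_is_L(self, geom):
        traj, tails = self.straight_chain_traj(geom, "z", L=1.2)
        prof = chain_elongation(traj, tails, geom, np.arange(0, 4.5, 0.5))
        occ = prof.occupied
        assert prof.elongation_sn1[occ][0] == pytest.approx(1.2, abs=1e-12)
        assert prof.elongation_sn2[occ][0] == pytest.approx(1.2, abs=1e-12)

    def test_xy_plane_chain_elongation_is_zero(self, geom):
        traj, tails = self.straight_chain_traj(geom, "xy", L=1.2)
        prof = chain_elongation(traj, tails, geom, np.arange(0, 4.5, 0.5))
        assert prof.elongation_sn1[prof.occupied][0] == pytest.approx(0.0, abs=1e-12)

    def test_random_coil_matches_bruteforce(self, geom):
        spec = SyntheticSpec(seed=12, n_lipids_per_leaflet=40)
        traj, info = gen_lipid_trajectory(spec, n_frames=8)
        bins = np.arange(0.5, 4.25, 0.5)
        prof = chain_elongation(traj, info["lipid_tails"], geom, bins)
        # brute force: recompute bin means directly from coordinates
        nb = bins.size - 1
        acc = [[[] for _ in range(nb)] for _ in range(2)]
        for t in range(traj.n_frames):
            for c2, sn1, sn2 in info["lipid_tails"]:
                p = traj.positions[t]
                rho = np.hypot(p[c2, 0] - geom.origin[0], p[c2, 1] - geom.origin[1])
                b = int(np.digitize(rho, bins)) - 1
                if 0 <= b < nb:
                    acc[0][b].append(abs(p[sn1[-1], 2] - p[sn1[0], 2]))
                    acc[1][b].append(abs(p[sn2[-1], 2] - p[sn2[0], 2]))
        for b in range(nb):
            if acc[0][b]:
                assert prof.elongation_sn1[b] == pytest.approx(
                    np.mean(acc[0][b]), rel=1e-9
                )
                assert prof.elongation_sn2[b] == pytest.approx(
                    np.mean(acc[1][b]), rel=1e-9
                )

    def test_monotone_profile_from_linear_trans_gradient(self, geom):
        spec = SyntheticSpec(seed=13)
        traj, info = gen_lipid_trajectory(spec, n_frames=30)
        prof = chain_elongation(
            traj, info["lipid_tails"], geom, np.arange(0.5, 4.25, 0.5)
        )
        e = prof.elongation_sn1[prof.occupied]
        assert np.all(np.diff(e) >= -2 * prof.se_sn1[prof.occupied][1:])
        # strictly increasing end to end
        assert e[-1] > e[0]

    def test_short_chain_rejected(self, geom):
        traj = make_traj(np.full(3, 6.0))
        with pytest.raises(DomainError):
            chain_elongation(
                traj, [(0, np.array([0]), np.array([0, 0]))], geom,
                np.arange(0, 2, 0.5),
            )


class TestBackboneRmsd:
    def make_ref(self, seed=0, n=8):
        rng = np.random.default_rng(seed)
        return rng.uniform(2, 8, (n, 3))

    def test_identity_is_zero(self):
        ref_pos = self.make_ref()
        traj = Trajectory(
            np.zeros(1), ref_pos[None], np.full(3, 10.0)
        )
        sel = Selection("bb", np.arange(8), "protein-backbone")
        ref = Frame(0.0, ref_pos, np.full(3, 10.0))
        for sup in (True, False):
            series = backbone_rmsd(traj, sel, ref, superpose=sup)
            assert series.rmsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_gives_zero_after_superposition(self):
        ref_pos = self.make_ref(1)
        theta = 0.7
        Rz = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = ref_pos @ Rz.T + np.array([0.5, -0.3, 1.1])
        traj = Trajectory(np.zeros(1), moved[None], np.full(3, 20.0))
        sel = Selection("bb", np.arange(8), "protein-backbone")
        ref = Frame(0.0, ref_pos, np.full(3, 20.0))
        assert backbone_rmsd(traj, sel, ref, superpose=True).rmsd[0] <= 1e-10
        assert backbone_rmsd(traj, sel, ref, superpose=False).rmsd[0] > 0.1

    def test_single_displaced_atom_without_superposition(self):
        ref_pos = self.make_ref(2)
        moved = ref_pos.copy()
        moved[3] += np.array([0.0, 0.0, 0.4])
        traj = Trajectory(np.zeros(1), moved[None], np.full(3, 10.0))
        sel = Selection("bb", np.arange(8), "protein-backbone")
        ref = Frame(0.0, ref_pos, np.full(3, 10.0))
        series = backbone_rmsd(traj, sel, ref, superpose=False)
        assert series.rmsd[0] == pytest.approx(0.4 / np.sqrt(8), rel=1e-12)

    def test_superposed_never_exceeds_raw(self):
        rng = np.random.default_rng(3)
        ref_pos = self.make_ref(3, n=12)
        frames = ref_pos[None] + rng.normal(0, 0.3, (6, 12, 3))
        traj = Trajectory(np.arange(6) * 0.1, frames, np.full(3, 10.0))
        sel = Selection("bb", np.arange(12), "protein-backbone")
        ref = Frame(0.0, ref_pos, np.full(3, 10.0))
        raw = backbone_rmsd(traj, sel, ref, superpose=False).rmsd
        sup = backbone_rmsd(traj, sel, ref, superpose=True).rmsd
        assert np.all(sup <= raw + 1e-12)

    def test_matches_mdanalysis_reference(self):
        # independent cross-check of the superposed RMSD
        from MDAnalysis.analysis import rms as mda_rms

        rng = np.random.default_rng(4)
        ref_pos = self.make_ref(4, n=20)
        mob = ref_pos + rng.normal(0, 0.2, (20, 3))
        traj = Trajectory(np.zeros(1), mob[None], np.full(3, 10.0))
        sel = Selection("bb", np.arange(20), "protein-backbone")
        ref = Frame(0.0, ref_pos, np.full(3, 10.0))
        ours = backbone_rmsd(traj, sel, ref, superpose=True).rmsd[0]
        theirs = mda_rms.rmsd(mob, ref_pos, center=True, superposition=True)
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_size_mismatch_rejected(self):
        traj = Trajectory(np.zeros(1), np.zeros((1, 4, 3)) + 1.0, np.full(3, 10.0))
        sel = Selection("bb", np.arange(4), "protein-backbone")
        ref = Frame(0.0, np.ones((3, 3)), np.full(3, 10.0))
        with pytest.raises(DomainError):
            backbone_rmsd(traj, sel, ref, reference_indices=np.arange(3))


def test_kabsch_reflection_guard():
    # a mirrored configuration must not be matched by an improper rotation
    ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    mirrored = ref * np.array([1, 1, -1.0])
    out = kabsch_superpose(mirrored, ref)
    rmsd = np.sqrt(np.mean(np.sum((out - ref) ** 2, axis=1)))
    assert rmsd > 0.1
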