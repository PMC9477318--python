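"""Mapping tables: grids, exclusion cone, inversion, regions, persistence."""

import numpy as np
import pytest

from whiskmap.errors import ParameterError, StateError, VersionError
from whiskmap.geometry import ContactPoint
from whiskmap.mapping import (MappingTable, TripletSpec, build_grid,
                              classify_region, flag_small_deflection, invert,
                              invert_many, reduced_grid,
                              small_deflection_mask)


class TestBuildGrid:
    def test_full_grid_count(self):
        grid = build_grid()
        assert len(grid) == 15 * 131 * 121 == 237_765

    def test_reduced_grid_count(self):
        grid = reduced_grid()
        assert len(grid) == 8 * 44 * 41

    def test_single_point(self):
        grid = build_grid((10, 10), 1, (0, 0), 1, (0, 0), 1)
        assert len(grid) == 1

    def test_empty_range_rejected(self):
        with pytest.raises(ParameterError):
            build_grid((10, 6), 1)
        with pytest.raises(ParameterError):
            build_grid(r_step=0.0)


class TestTripletSpec:
    def test_valid(self):
        spec = TripletSpec(("Fx", "MB", "MD"))
        assert spec.key == "Fx-MB-MD"

    @pytest.mark.parametrize("names", [
        ("Fx", "Fx", "MB"), ("Fx", "MB"), ("Fx", "MB", "XX"),
    ])
    def test_invalid(self, names):
        with pytest.raises(ParameterError):
            TripletSpec(names)


class TestSmallDeflectionCone:
    def test_on_whisker_excluded(self, gamma_whisker):
        node = gamma_whisker.nodes[50]
        from whiskmap.geometry import cartesian_to_spherical

        assert flag_small_deflection(cartesian_to_spherical(node),
                                     gamma_whisker)

    def test_threshold_formula(self):
        """s_closest·tan(2°) at s=10 mm is ≈0.349 mm."""
        import whiskmap.geometry as geo

        n = 101
        nodes = np.column_stack([np.linspace(0, 20, n), np.zeros(n),
                                 np.zeros(n)])
        w = geo.WhiskerShape(nodes, np.linspace(0, 20, n),
                             np.linspace(100, 100 / 15, n),
                             geo.MaterialParams())
        near = np.array([[10.0, 0.30, 0.0]])
        far = np.array([[10.0, 1.00, 0.0]])
        assert small_deflection_mask(near, w)[0]
        assert not small_deflection_mask(far, w)[0]

    def test_shrinking_cone_never_excludes_more(self, micro_table,
                                                gamma_whisker):
        from whiskmap.geometry import spherical_grid_to_cartesian

        df = micro_table.df
        xyz = spherical_grid_to_cartesian(df["r_mm"], df["theta_deg"],
                                          df["phi_deg"])
        m2 = small_deflection_mask(xyz, gamma_whisker, 2.0)
        m1 = small_deflection_mask(xyz, gamma_whisker, 1.0)
        assert not np.any(m1 & ~m2)  # 1° cone is a subset of the 2° cone


class TestInvert:
    def test_exact_record_short_circuit(self, micro_table):
        spec = TripletSpec(("Fx", "MB", "MD"))
        row = micro_table.retained().iloc[10]
        cp, diag = invert((row["Fx"], row["MB"], row["MD_rad"]),
                          micro_table, spec)
        assert cp.r_mm == row["r_mm"]
        assert cp.theta_deg == row["theta_deg"]
        assert cp.phi_deg == row["phi_deg"]
        assert diag["nearest_distance"] < 1e-12
        assert not diag["extrapolated"]

    def test_far_query_flagged_extrapolated(self, micro_table):
        spec = TripletSpec(("Fx", "MB", "MD"))
        cp, diag = invert((1e5, 1e6, 0.0), micro_table, spec)
        assert diag["extrapolated"]
        assert np.isfinite(cp.r_mm)  # estimate still returned

    def test_batch_matches_single(self, micro_table):
        spec = TripletSpec(("Fx", "MB", "MD"))
        ret = micro_table.retained()
        q = ret[["Fx", "MB", "MD_rad"]].to_numpy()[:5]
        batch = invert_many(q, micro_table, spec)
        for i in range(5):
            cp, _ = invert(q[i], micro_table, spec)
            assert batch["r_mm"].iloc[i] == pytest.approx(cp.r_mm)

    def test_missing_fingerprint_rejected(self, micro_table):
        t = MappingTable(micro_table.df,
                         {k: v for k, v in micro_table.meta.items()
                          if k != "whisker_fingerprint"})
        with pytest.raises(StateError):
            invert((0.0, 1.0, 0.0), t, TripletSpec(("Fx", "MB", "MD")))


class TestRegions:
    def test_sign_convention(self):
        rec = {"converged": True, "tangent_x": 0.8, "theta_deg": -10.0}
        assert classify_region(rec) == "cf"
        rec["theta_deg"] = 10.0
        assert classify_region(rec) == "cb"
        rec["tangent_x"] = -0.2
        assert classify_region(rec) == "ld"

    def test_missing_metadata(self):
        with pytest.raises(StateError):
            classify_region({"converged": True, "tangent_x": np.nan,
                             "theta_deg": 0.0})

    def test_partition(self, micro_table):
        d = micro_table.df[micro_table.df["converged"]]
        assert set(d["region"]) <= {"cf", "cb", "ld"}
        assert (d["region"] != "").all()

    def test_fd_rotates_sharply_into_large_deflection(self, gamma_rod):
        """Driving a contact toward the parallel-to-y-z orientation rotates
        the transverse-force direction rapidly away from its
        small-deflection branch; contacts past that orientation are
        classified large-deflection."""
        from whiskmap.geometry import spherical_to_cartesian
        from whiskmap.signals import decompose

        warm = None
        fd_mid = None
        fd_ld = None
        for ph in np.arange(0.0, 44.5, 1.0):
            res = gamma_rod.deflect(spherical_to_cartesian(
                ContactPoint(8.0, 10.0, float(ph))), warm=warm)
            if not res.converged:
                continue
            warm = gamma_rod.last_state
            sig = decompose(res.base_loads)
            if ph == 30.0:
                fd_mid = sig.FD
            if res.contact_tangent[0] < 0:
                fd_ld = sig.FD
        assert fd_ld is not None, "no large-deflection contact converged"
        rot = np.degrees(abs(np.angle(np.exp(1j * (fd_ld - fd_mid)))))
        assert rot > 45.0


class TestPersistence:
    def test_csv_round_trip(self, micro_table, tmp_path):
        p = tmp_path / "t.csv"
        micro_table.save_csv(p)
        back = MappingTable.load(p)
        assert len(back.df) == len(micro_table.df)
        for col in ("r_mm", "Fx", "MB", "MD_rad", "converged",
                    "excluded_small_deflection"):
            np.testing.assert_allclose(
                back.df[col].to_numpy(float),
                micro_table.df[col].to_numpy(float), atol=1e-12)
        assert back.meta["whisker_fingerprint"] == \
            micro_table.meta["whisker_fingerprint"]

    def test_hdf5_matches_csv(self, micro_table, tmp_path):
        pc, ph = tmp_path / "t.csv", tmp_path / "t.h5"
        micro_table.save_csv(pc)
        micro_table.save_hdf5(ph)
        a = MappingTable.load(pc)
        b = MappingTable.load(ph)
        for col in ("r_mm", "theta_deg", "phi_deg", "Fx", "MB", "MD_rad"):
            np.testing.assert_allclose(a.df[col].to_numpy(float),
                                       b.df[col].to_numpy(float), atol=1e-12)

    def test_future_version_rejected(self, micro_table, tmp_path):
        p = tmp_path / "t.csv"
        micro_table.save_csv(p)
        text = p.read_text().replace("v1", "v99", 1)
        p.write_text(text)
        with pytest.raises(VersionError):
            MappingTable.load(p)

    def test_duplicate_grid_coordinates_rejected(self, micro_table):
        import pandas as pd

        df = pd.concat([micro_table.df, micro_table.df.iloc[[0]]])
        with pytest.raises(ParameterError):
            MappingTable(df, micro_table.meta)
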