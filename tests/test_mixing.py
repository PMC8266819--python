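"""TEF correction, concentration-weighted mixture moments and simulated
mixing polygons."""

import numpy as np
import pandas as pd
import pytest

from hairsimm.mixing import (
    DEFAULT_TEFS,
    MixingSpace,
    apply_tef,
    build_mixing_space,
    mixture_mean,
    mixture_moments,
    simulate_mixing_polygons,
)
from hairsimm.sources import SourceCategory


def _cat(name="Herbs", cls="vegetable", **kw):
    defaults = dict(
        mean_d13C=-30.1, sd_d13C=1.6, mean_d15N=-2.2, sd_d15N=1.8,
        n=63, digest_c=45.9, digest_n=2.7,
    )
    defaults.update(kw)
    return SourceCategory(name=name, trophic_class=cls, **defaults)


class TestTefCorrection:
    def test_vegetable_shift(self):
        corr = apply_tef(_cat(), DEFAULT_TEFS["vegetable"])
        assert corr.mean_d13C == pytest.approx(-30.1 + 3.4)
        assert corr.mean_d13C == pytest.approx(-26.7)
        assert corr.sd_d13C == pytest.approx(np.hypot(1.6, 0.5))

    def test_animal_shift(self):
        ung = _cat("Ungulates", "animal", mean_d15N=4.3)
        corr = apply_tef(ung, DEFAULT_TEFS["animal"])
        assert corr.mean_d15N == pytest.approx(4.3 + 3.9)
        assert corr.mean_d15N == pytest.approx(8.2)

    def test_zero_tef_sd_keeps_source_sd(self):
        tef = DEFAULT_TEFS["vegetable"].__class__("vegetable", 3.4, 0.0, 2.4, 0.0)
        corr = apply_tef(_cat(), tef)
        assert corr.sd_d13C == pytest.approx(1.6)
        assert corr.sd_d15N == pytest.approx(1.8)

    def test_class_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_tef(_cat(), DEFAULT_TEFS["animal"])

    def test_space_excludes_c4_and_orders_sources(self, categories):
        space = build_mixing_space(categories)
        assert "C4" not in space.names
        assert list(space.names) == sorted(space.names)
        assert space.n_sources == 7
        # corrected variances never fall below raw variances
        raw = {c.name: (c.sd_d13C, c.sd_d15N) for c in categories}
        for i, name in enumerate(space.names):
            assert space.sds[i, 0] >= raw[name][0]
            assert space.sds[i, 1] >= raw[name][1]


class TestMixtureMoments:
    def test_hand_computed_concentration_weighting(self):
        """p=(0.5, 0.5), q=(2, 1), corrected means (0, 3):
        (0.5*2*0 + 0.5*1*3) / (0.5*2 + 0.5*1) = 1.0"""
        space = MixingSpace(
            season=None, names=("a", "b"),
            means=np.array([[0.0, 0.0], [3.0, 3.0]]),
            sds=np.zeros((2, 2)),
            conc=np.array([[2.0, 2.0], [1.0, 1.0]]),
        )
        assert mixture_mean([0.5, 0.5], space, "d13C") == pytest.approx(1.0)

    def test_vertex_returns_source_mean(self, space):
        for k in range(space.n_sources):
            p = np.zeros(space.n_sources)
            p[k] = 1.0
            mean, _ = mixture_moments(p, space)
            np.testing.assert_allclose(mean, space.means[k], atol=1e-12)

    def test_equal_concentrations_reduce_to_plain_average(self):
        space = MixingSpace(
            season=None, names=("a", "b", "c"),
            means=np.array([[-30.0, 1.0], [-25.0, 4.0], [-20.0, 7.0]]),
            sds=np.zeros((3, 2)),
            conc=np.full((3, 2), 5.0),
        )
        p = np.array([0.2, 0.3, 0.5])
        mean, _ = mixture_moments(p, space)
        np.testing.assert_allclose(mean, p @ space.means, atol=1e-12)

    def test_invariant_to_common_concentration_rescaling(self, space):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(space.n_sources))
        m1, v1 = mixture_moments(p, space)
        scaled = MixingSpace(
            season=space.season, names=space.names, means=space.means,
            sds=space.sds, conc=space.conc * 7.3,
        )
        m2, v2 = mixture_moments(p, scaled)
        np.testing.assert_allclose(m1, m2, atol=1e-10)
        np.testing.assert_allclose(v1, v2, atol=1e-10)


def _point_in_polygon(point, vertices):
    """Independent ray-crossing oracle (closed boundary)."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # boundary check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xin:
                inside = not inside
    return inside


class TestMixingPolygons:
    def _consumers(self, pts):
        return pd.DataFrame(
            {"consumer_id": [f"c{i}" for i in range(len(pts))],
             "d13C": [p[0] for p in pts], "d15N": [p[1] for p in pts]}
        )

    def test_centroid_always_inside(self):
        """For sources well separated relative to their SDs the centroid of
        the corrected means is inside essentially every simulated hull."""
        wide = MixingSpace(
            season=None, names=("a", "b", "c", "d"),
            means=np.array([[-30.0, 0.0], [-10.0, 0.0], [-20.0, 15.0], [-20.0, -15.0]]),
            sds=np.full((4, 2), 0.5),
            conc=np.ones((4, 2)),
        )
        centroid = wide.means.mean(axis=0)
        rep = simulate_mixing_polygons(
            wide, self._consumers([centroid]), n_iter=1000, seed=3
        )
        assert rep["inside_probability"].iloc[0] >= 0.99
        assert not rep["excluded"].iloc[0]

    def test_far_point_never_inside(self, space):
        rep = simulate_mixing_polygons(
            space, self._consumers([(0.0, 50.0)]), n_iter=200, seed=3
        )
        assert rep["inside_probability"].iloc[0] == 0.0
        assert rep["excluded"].iloc[0]

    def test_zero_variance_matches_point_in_polygon_oracle(self, space):
        """With all source SDs zero the hull is fixed, so the Monte-Carlo
        probability must be exactly 0 or 1 and agree with a ray-crossing
        oracle on the hull of the corrected means."""
        import shapely

        frozen = MixingSpace(
            season=None, names=space.names, means=space.means,
            sds=np.zeros_like(space.sds), conc=space.conc,
        )
        hull = shapely.convex_hull(shapely.multipoints(frozen.means))
        vertices = list(hull.exterior.coords)[:-1]
        rng = np.random.default_rng(5)
        pts = [
            (rng.uniform(-35, -15), rng.uniform(-5, 15)) for _ in range(40)
        ] + [tuple(v) for v in vertices]  # boundary points count as inside
        rep = simulate_mixing_polygons(frozen, self._consumers(pts), n_iter=3, seed=0)
        for point, prob in zip(pts, rep["inside_probability"]):
            assert prob in (0.0, 1.0)
            assert bool(prob) == _point_in_polygon(point, vertices), point

    def test_seeded_reproducibility(self, space):
        cons = self._consumers([(-24.0, 3.0), (-22.0, 5.0)])
        a = simulate_mixing_polygons(space, cons, n_iter=300, seed=11)
        b = simulate_mixing_polygons(space, cons, n_iter=300, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_sources_rejected(self):
        tiny = MixingSpace(
            season=None, names=("a", "b"),
            means=np.zeros((2, 2)), sds=np.zeros((2, 2)), conc=np.ones((2, 2)),
        )
        with pytest.raises(ValueError, match="3 sources"):
            simulate_mixing_polygons(tiny, self._consumers([(0, 0)]), n_iter=10)
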