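"""Selective fusion: criteria, ranking, fusion semantics, oracle equivalence."""

import numpy as np
import pytest
from skimage.draw import disk
from skimage.measure import perimeter_crofton as sk_perimeter

from cacseg.fusion import (EnsemblePrediction, FusionConfig, RegionScore,
                           candidate_regions, fuse_volume,
                           morphological_consistency, rank_and_select,
                           selective_fuse, soft_vote, topological_continuity,
                           vessel_conformity)
from cacseg.preprocess import ConfigError


# ---------------------------------------------------------------------------
# independent brute-force reference implementation (loops + flood fill)
# ---------------------------------------------------------------------------

def _flood_components(mask):
    """8-connected components by BFS; no scipy."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        comp = np.zeros_like(mask)
        stack = [(sy, sx)]
        seen[sy, sx] = True
        while stack:
            y, x = stack.pop()
            comp[y, x] = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                            and mask[ny, nx] and not seen[ny, nx]):
                        seen[ny, nx] = True
                        stack.append((ny, nx))
        comps.append(comp)
    return comps


def _bf_morph(mask):
    comps = _flood_components(mask)
    if not comps:
        return 0.0
    num = den = 0.0
    for c in comps:
        a = float(c.sum())
        p = float(sk_perimeter(c, directions=4))
        circ = 1.0 if p <= 0 else min(4 * np.pi * a / p ** 2, 1.0)
        num += a * circ
        den += a
    return min(num / den, 1.0)


def _bf_topo(mask, s_min):
    comps = _flood_components(mask)
    total = sum(c.sum() for c in comps)
    if total == 0:
        return 0.0
    big = sum(c.sum() for c in comps if c.sum() >= s_min)
    return float(big / total)


def _bf_vessel(mask, prior):
    fg = mask.sum()
    if fg == 0:
        return 0.0
    if prior is None:
        return 1.0
    return float((mask & prior).sum() / fg)


def brute_force_selective(maps, prior, cfg: FusionConfig):
    """Naive re-implementation of the whole fusion rule."""
    bins = [np.asarray(m) >= cfg.member_threshold for m in maps]
    union = np.zeros_like(bins[0])
    for b in bins:
        union = union | b
    regions = _flood_components(union)
    fused = np.zeros(union.shape, dtype=np.float32)
    wm, wt, wv = cfg.weights
    for region in regions:
        combined = []
        for i, b in enumerate(bins):
            r = b & region
            score = (wm * _bf_morph(r) + wt * _bf_topo(r, cfg.s_min)
                     + wv * _bf_vessel(r, prior if cfg.use_prior else None))
            combined.append((score, i))
        ranked = sorted(combined, key=lambda t: (-t[0], t[1]))
        chosen = sorted(i for s, i in ranked[:cfg.top_k] if s > 0)
        if not chosen:
            continue
        acc = np.zeros(union.shape, dtype=np.float64)
        for i in chosen:
            acc += np.asarray(maps[i], dtype=np.float32)
        fused[region] = (acc[region] / len(chosen)).astype(np.float32)
    mask = fused >= cfg.output_threshold
    if cfg.use_prior and prior is not None:
        mask = mask & prior
        fused = np.where(prior, fused, 0.0)
    return fused, mask


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------

def _pred(*maps, members=()):
    return EnsemblePrediction(tuple(np.asarray(m, np.float32) for m in maps),
                              tuple(members))


def test_regions_disjoint_blobs():
    a = np.zeros((8, 8)); a[1:3, 1:3] = 1
    b = np.zeros((8, 8)); b[5:7, 5:7] = 1
    regions = candidate_regions(_pred(a, b), 0.5)
    assert len(regions) == 2


def test_regions_overlap_merges():
    a = np.zeros((8, 8)); a[2:5, 2:5] = 1
    b = np.zeros((8, 8)); b[4:7, 4:7] = 1
    assert len(candidate_regions(_pred(a, b), 0.5)) == 1


def test_regions_empty():
    z = np.zeros((8, 8))
    assert candidate_regions(_pred(z, z), 0.5) == []
    fused, mask, _ = selective_fuse(_pred(z, z))
    assert not mask.any() and not fused.any()


def test_every_positive_voxel_in_exactly_one_region(rng):
    maps = [rng.uniform(size=(12, 12)) for _ in range(3)]
    preds = _pred(*maps)
    regions = candidate_regions(preds, 0.5)
    union = np.zeros((12, 12), dtype=int)
    for r in regions:
        union += r.astype(int)
    expected = np.zeros((12, 12), dtype=bool)
    for m in maps:
        expected |= m >= 0.5
    assert np.array_equal(union > 0, expected)
    assert union.max() <= 1


# ---------------------------------------------------------------------------
# the three criteria
# ---------------------------------------------------------------------------

def test_morph_disk_compact():
    mask = np.zeros((16, 16), dtype=bool)
    rr, cc = disk((8, 8), 5.5)
    mask[rr, cc] = True
    score = morphological_consistency(mask)
    assert score > 0.8
    assert score == pytest.approx(_bf_morph(mask))


def test_morph_thin_line_low():
    mask = np.zeros((8, 24), dtype=bool)
    mask[4, 2:22] = True     # 1 px x 20 px line
    assert morphological_consistency(mask) < 0.5


def test_morph_empty_zero():
    assert morphological_consistency(np.zeros((5, 5), bool)) == 0.0


def test_topo_single_large_component():
    mask = np.zeros((10, 10), bool)
    mask[2:7, 2:12] = True
    mask = mask[:, :10]
    assert topological_continuity(mask, 3) == 1.0


def test_topo_all_fragments():
    mask = np.zeros((10, 20), bool)
    mask[::3, ::2] = False
    for i in range(10):
        mask[(i * 2) % 9, (i * 3) % 19] = True
    # force isolation: rebuild as strictly isolated voxels
    mask = np.zeros((10, 20), bool)
    for i in range(10):
        mask[(i % 5) * 2, i * 2] = True
    assert topological_continuity(mask, 3) == 0.0


def test_topo_nine_plus_one():
    mask = np.zeros((8, 8), bool)
    mask[0:3, 0:3] = True    # 9 voxels
    mask[6, 6] = True        # isolated single
    assert topological_continuity(mask, 3) == pytest.approx(0.9)


def test_vessel_conformity_cases():
    prior = np.zeros((6, 6), bool)
    prior[:, :3] = True
    inside = np.zeros((6, 6), bool); inside[1:3, 1:3] = True
    outside = np.zeros((6, 6), bool); outside[1:3, 4:6] = True
    assert vessel_conformity(inside, prior) == 1.0
    assert vessel_conformity(outside, prior) == 0.0
    mixed = np.zeros((6, 6), bool)
    mixed[0, 0] = mixed[0, 1] = mixed[0, 2] = True   # in
    mixed[0, 4] = True                               # out
    assert vessel_conformity(mixed, prior) == 0.75
    assert vessel_conformity(np.zeros((6, 6), bool), prior) == 0.0
    assert vessel_conformity(inside, None) == 1.0
    with pytest.raises(ValueError):
        vessel_conformity(inside, prior[:3])


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _scores(combined_list):
    return [RegionScore(0, f"m{i}", 0, 0, 0, c) for i, c in enumerate(combined_list)]


def test_rank_tie_break_fixed_member_order():
    out = rank_and_select(_scores([0.5, 0.5, 0.5, 0.5]),
                          FusionConfig(top_k=2), 4)
    assert [s.selected for s in out] == [True, True, False, False]


def test_rank_zero_score_excluded_regardless_of_k():
    out = rank_and_select(_scores([0.0, 0.0]), FusionConfig(top_k=2), 2)
    assert not any(s.selected for s in out)


def test_rank_simple_sort():
    out = rank_and_select(_scores([0.9, 0.5, 0.2]), FusionConfig(top_k=2), 3)
    assert [s.selected for s in out] == [True, True, False]


def test_rank_top_k_exceeds_members():
    with pytest.raises(ConfigError):
        rank_and_select(_scores([0.5, 0.5]), FusionConfig(top_k=3), 2)


# ---------------------------------------------------------------------------
# fusion semantics
# ---------------------------------------------------------------------------

def test_agreement_limit_identical_members(rng):
    p = (rng.uniform(size=(10, 10)) * 0.9).astype(np.float32)
    p[2:5, 2:5] = 0.9
    preds = _pred(p, p, p, p)
    fused, mask, _ = selective_fuse(preds, cfg=FusionConfig(use_prior=False))
    sv_prob, sv_mask = soft_vote(preds)
    assert np.array_equal(mask, sv_mask)
    assert np.array_equal(mask, p >= 0.5)
    # fused probability equals the shared map on candidate regions
    regions = candidate_regions(preds, 0.5)
    for r in regions:
        assert np.allclose(fused[r], p[r])


def test_noise_member_excluded_by_rank():
    """Two coherent members plus one speckle member adjacent to the lesion:
    the speckles drag that member's rank down and the clean pair wins."""
    a = np.zeros((8, 8), np.float32)
    a[2:5, 2:5] = 0.9
    b = a.copy()
    c = np.zeros((8, 8), np.float32)
    c[1, 1] = c[5, 5] = c[1, 5] = 0.9   # singles touching the blob region
    preds = _pred(a, b, c)
    cfg = FusionConfig(top_k=2, use_prior=False)
    fused, mask, scores = selective_fuse(preds, cfg=cfg)
    sel = {s.member for s in scores.scores if s.selected}
    assert sel == {"member0", "member1"}
    assert np.array_equal(mask, a >= 0.5)
    bf_fused, bf_mask = brute_force_selective([a, b, c], None, cfg)
    assert np.array_equal(mask, bf_mask)
    assert np.allclose(fused, bf_fused)


def test_prior_constraint_removes_outside_decoy():
    prior = np.zeros((8, 8), bool)
    prior[:, :4] = True
    a = np.zeros((8, 8), np.float32)
    a[1:3, 1:3] = 0.9      # inside prior
    a[5:7, 5:7] = 0.9      # decoy outside prior
    preds = _pred(a, a)
    fused, mask, _ = selective_fuse(preds, prior, FusionConfig(use_prior=True))
    assert not (mask & ~prior).any()
    assert mask[1:3, 1:3].all()
    assert not fused[~prior].any()


def test_soft_vote_mean():
    a = np.full((4, 4), 0.2, np.float32)
    b = np.full((4, 4), 0.4, np.float32)
    c = np.full((4, 4), 0.6, np.float32)
    prob, mask = soft_vote(_pred(a, b, c))
    assert np.allclose(prob, 0.4)
    assert not mask.any()
    prob2, _ = soft_vote(_pred(b, np.zeros((4, 4), np.float32)))
    assert np.allclose(prob2, 0.2)


def test_prior_guarantee_exact_for_random_inputs(rng):
    for _ in range(20):
        maps = [(rng.uniform(size=(9, 9)) > 0.6) * rng.uniform(0.5, 1.0)
                for _ in range(3)]
        prior = rng.uniform(size=(9, 9)) > 0.5
        _, mask, _ = selective_fuse(_pred(*maps), prior,
                                    FusionConfig(use_prior=True))
        assert not (mask & ~prior).any()


def test_member_permutation_changes_only_tie_breaks(rng):
    maps = [np.round(rng.uniform(size=(10, 10)), 1).astype(np.float32)
            for _ in range(4)]
    cfg = FusionConfig(use_prior=False, top_k=2)
    _, mask_a, sa = selective_fuse(_pred(*maps), cfg=cfg)
    perm = [maps[1], maps[0], maps[3], maps[2]]
    _, mask_b, sb = selective_fuse(_pred(*perm), cfg=cfg)
    # combined scores per (region, underlying member) are permutation
    # invariant; masks may differ only where exact ties were re-broken
    ties = set()
    for s in sa.scores:
        peers = [t for t in sa.for_region(s.region_id)
                 if t.combined == s.combined and t.member != s.member]
        if peers:
            ties.add(s.region_id)
    if not ties:
        assert np.array_equal(mask_a, mask_b)


@pytest.mark.parametrize("seed", range(30))
def test_matches_bruteforce_oracle_random_toys(seed):
    """Random <=8x8 ensembles: implementation == naive reference, exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 5))
    h, w = int(rng.integers(4, 9)), int(rng.integers(4, 9))
    maps = [np.round(rng.uniform(size=(h, w)), 2).astype(np.float32)
            for _ in range(n)]
    prior = rng.uniform(size=(h, w)) > 0.4 if rng.random() < 0.7 else None
    cfg = FusionConfig(top_k=int(rng.integers(1, n + 1)),
                       s_min=int(rng.integers(1, 4)),
                       use_prior=prior is not None)
    fused, mask, _ = selective_fuse(_pred(*maps), prior, cfg)
    bf_fused, bf_mask = brute_force_selective(maps, prior, cfg)
    assert np.array_equal(mask, bf_mask)
    assert np.allclose(fused, bf_fused, atol=1e-6)


def test_fuse_volume_2d_matches_per_slice(rng):
    vols = [rng.uniform(size=(3, 8, 8)).astype(np.float32) for _ in range(3)]
    prior = rng.uniform(size=(3, 8, 8)) > 0.5
    cfg = FusionConfig()
    fused, mask = fuse_volume(vols, prior, cfg)
    for z in range(3):
        fz, mz, _ = selective_fuse(_pred(*(v[z] for v in vols)), prior[z], cfg)
        assert np.array_equal(mask[z], mz)
        assert np.allclose(fused[z], fz)


def test_ensemble_validation():
    with pytest.raises(ValueError):
        EnsemblePrediction((np.zeros((4, 4), np.float32),))
    with pytest.raises(ValueError):
        _pred(np.zeros((4, 4)), np.full((4, 4), 1.5))
    with pytest.raises(ConfigError):
        FusionConfig(weights=(0.5, 0.5, 0.5))
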