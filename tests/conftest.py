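import heapq

import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(16, 16), density=0.45, smooth=1.2):
    """Random non-empty binary mask (thresholded smoothed noise); falls back
    to a single pixel if the threshold empties it."""
    field = ndimage.gaussian_filter(rng.random(shape), smooth)
    mask = field > np.quantile(field, 1 - density)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


def random_connected_mask(rng, shape=(24, 24)):
    """Largest 8-connected component of a random blob mask."""
    from skimage.measure import label

    mask = random_blob_mask(rng, shape)
    lab = label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def crescent_mask(shape, center, r_in, r_out, a0, a1):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy, dx = rr - center[0], cc - center[1]
    radius = np.hypot(dy, dx)
    ang = np.rad2deg(np.arctan2(dy, dx))
    rel = (ang - a0) % 360.0
    span = (a1 - a0) % 360.0 or 360.0
    return (radius >= r_in) & (radius <= r_out) & (rel <= span)


def dijkstra_geodesic(mask, sources):
    """Independent brute-force geodesic distance: 8-connected Dijkstra with
    Euclidean step weights, pure Python heapq."""
    mask = np.asarray(mask, bool)
    dist = np.full(mask.shape, np.inf)
    heap = []
    for r, c in np.argwhere(np.asarray(sources, bool) & mask):
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, int(r), int(c)))
    offs = [
        (-1, -1, np.sqrt(2)), (-1, 0, 1.0), (-1, 1, np.sqrt(2)),
        (0, -1, 1.0), (0, 1, 1.0),
        (1, -1, np.sqrt(2)), (1, 0, 1.0), (1, 1, np.sqrt(2)),
    ]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, w in offs:
            nr, nc = r + dr, c + dc
            if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1] and mask[nr, nc]:
                nd = d + w
                if nd < dist[nr, nc] - 1e-15:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, nr, nc))
    return dist


def neighbor_scan_superficial(mask):
    """Brute-force per-pixel scan: ROI pixels with any of their 8 neighbors
    outside the ROI (image border counts as outside)."""
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, bool)
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            surface = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if nr < 0 or nr >= rows or nc < 0 or nc >= cols or not mask[nr, nc]:
                        surface = True
            out[r, c] = surface
    return out


def brute_force_point_in_polygon(vertices, shape):
    """Even-odd rule at pixel centers via angle-independent crossing count
    along the +col direction (independent of the implementation's +row ray)."""
    verts = [tuple(map(float, v)) for v in vertices]
    n = len(verts)
    mask = np.zeros(shape, bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            crossings = 0
            on_edge = False
            for i in range(n):
                r1, c1 = verts[i]
                r2, c2 = verts[(i + 1) % n]
                # point-on-segment check
                d = abs((r2 - r1) * (c - c1) - (c2 - c1) * (r - r1))
                L2 = (r2 - r1) ** 2 + (c2 - c1) ** 2
                if L2 > 0:
                    t = ((r - r1) * (r2 - r1) + (c - c1) * (c2 - c1)) / L2
                    if d < 1e-9 and 0 <= t <= 1:
                        on_edge = True
                if (r1 > r) != (r2 > r):
                    c_at = (c2 - c1) * (r - r1) / (r2 - r1) + c1
                    if c < c_at:
                        crossings += 1
            mask[r, c] = on_edge or (crossings % 2 == 1)
    return mask
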