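import numpy as np
import pytest

from msmseg.oversegmentation import SuperpixelGraph


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_u8(rng):
    return rng.integers(0, 256, size=(16, 16)).astype(np.uint8)


def strip_graph(means, height=4, width_per=3, areas=None):
    """Build a SuperpixelGraph of vertical strips with the given means.

    The label map is synthetic; ``mean_intensity`` is set directly so merge
    arithmetic can be checked against hand computations.
    """
    k = len(means)
    if areas is None:
        areas = [height * width_per] * k
    cols = []
    for i, a in enumerate(areas):
        w = a // height
        cols.append(np.full((height, w), i, dtype=np.int64))
    labels = np.concatenate(cols, axis=1)
    adjacency = frozenset((i, i + 1) for i in range(k - 1))
    return SuperpixelGraph(labels=labels,
                           mean_intensity=np.asarray(means, dtype=float),
                           area_px=np.asarray(areas),
                           adjacency=adjacency)


def tophat_oracle(img, se_mask):
    """Definitional plateau transform via brute-force min/max filters.

    Border handling is edge-repeating reflection (np.pad "symmetric"),
    matching scipy.ndimage's "reflect" mode.
    """
    img = img.astype(np.int64)
    r = se_mask.shape[0] // 2
    h, w = img.shape

    def filt(fn, arr):
        out = np.empty((h, w), dtype=np.int64)
        for y in range(h):
            for x in range(w):
                window = arr[y:y + 2 * r + 1, x:x + 2 * r + 1]
                out[y, x] = fn(window[se_mask])
        return out

    def erode(arr):
        return filt(np.min, np.pad(arr, r, mode="symmetric"))

    def dilate(arr):
        return filt(np.max, np.pad(arr, r, mode="symmetric"))

    opening = dilate(erode(img))
    closing = erode(dilate(img))
    out = img + (img - opening) + (closing - img)
    return np.clip(out, 0, 255).astype(np.uint8)
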