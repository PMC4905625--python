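import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tuberhist.synthdata import ObjectSpec, PhantomSpec, render_slide_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def brute_force_count(image, tissue_mask, blue_threshold, min_area, max_area):
    """Independent object counter: plain-numpy positivity rule plus a
    stack-based 8-connected flood fill and the size gate. Kept free of the
    production labeling path so it can serve as an oracle."""
    img = np.asarray(image)
    red = img[..., 0].astype(int)
    blue = img[..., 2].astype(int)
    pos = tissue_mask & (blue <= blue_threshold) & (red > blue)
    H, W = pos.shape
    seen = np.zeros_like(pos, dtype=bool)
    hi = np.inf if max_area is None else max_area
    count = 0
    for r0 in range(H):
        for c0 in range(W):
            if not pos[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            area = 0
            while stack:
                r, c = stack.pop()
                area += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < H and 0 <= cc < W
                                and pos[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if min_area <= area <= hi:
                count += 1
    return count


@pytest.fixture
def neun_phantom():
    """Five disjoint 200-px NeuN objects in a 256x256 phantom."""
    spec = PhantomSpec(
        width_px=256, height_px=256,
        objects=[ObjectSpec("NeuN", 5, (200, 200))],
    )
    return render_slide_phantom(spec, seed=11)


@pytest.fixture
def diffuse_phantom():
    """A quarter of the tissue diffusely MBP-positive at OD log10(2)."""
    spec = PhantomSpec(
        width_px=192, height_px=192,
        diffuse_positive_fraction=0.25,
        diffuse_mean_od=0.30103,
    )
    return render_slide_phantom(spec, seed=12)
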