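import numpy as np
import pytest

from mitoscape import VoxelSpacing, phantoms


@pytest.fixture(scope="session")
def iso01():
    return VoxelSpacing(0.1, 0.1, 0.1)


@pytest.fixture(scope="session")
def iso005():
    return VoxelSpacing(0.05, 0.05, 0.05)


@pytest.fixture(scope="session")
def rgc():
    """Rasterized apical-progenitor phantom (soma + apical/basal process + stub)."""
    return phantoms.rasterize(phantoms.rgc_phantom())


@pytest.fixture(scope="session")
def rgc_annotation(rgc):
    from mitoscape import apical_progenitor_compartment_annotation

    return apical_progenitor_compartment_annotation(
        rgc.cell, rgc.soma, rgc.landmark, rgc.cell.spacing
    )


@pytest.fixture(scope="session")
def hek():
    """Round-cell phantom holding one punctus, one rod, one network."""
    return phantoms.rasterize(phantoms.hek_phantom())


def straight_tube(n_len=100, radius=3, pad=1):
    """Solid axis-aligned tube along x; returns (mask, end_slice_marker)."""
    side = 2 * radius + 1 + 2 * pad
    c = side // 2
    zz, yy = np.mgrid[0:side, 0:side]
    disk = (zz - c) ** 2 + (yy - c) ** 2 <= radius**2
    mask = np.broadcast_to(disk[:, :, None], (side, side, n_len)).copy()
    marker = np.zeros_like(mask)
    marker[:, :, 0] = mask[:, :, 0]
    return mask, marker


def u_tube(arm_vox=50, base_vox=19, radius=2):
    """U-shaped tube (two arms joined by a base); returns (mask, tip_a, tip_b).

    Arms run along z, the base along x; tips are the far arm-end centers.
    """
    nz = arm_vox + 3 * radius + 2
    nx = base_vox + 2 * radius + 3
    ny = 2 * radius + 3
    cy = ny // 2
    xa, xb = radius + 1, radius + 1 + base_vox
    zlo, zhi = radius + 1, radius + 1 + arm_vox
    mask = np.zeros((nz, ny, nx), bool)
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]

    def seg(p0, p1):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        n = int(np.ceil(np.linalg.norm(p1 - p0))) * 2 + 1
        for t in np.linspace(0, 1, n):
            c = p0 + t * (p1 - p0)
            mask[(zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2] = True

    seg((zhi, cy, xa), (zlo, cy, xa))
    seg((zlo, cy, xa), (zlo, cy, xb))
    seg((zlo, cy, xb), (zhi, cy, xb))
    return mask, (zhi, cy, xa), (zhi, cy, xb)
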