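import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_multimodel_pdb(path, frames, resids=None, chains=None):
    """Write (F, N, 3) coords as a multi-model CA-only PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    resids = np.arange(1, n + 1) if resids is None else np.asarray(resids)
    chains = np.array(["A"] * n) if chains is None else np.asarray(chains)
    atoms = struc.AtomArray(n)
    atoms.coord = frames[0]
    atoms.chain_id = chains
    atoms.res_id = resids
    atoms.res_name = np.array(["ALA"] * n)
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    stack = struc.stack([atoms] * len(frames))
    stack.coord = frames
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))
    return str(path)


def write_xyz(path, frames):
    """Write (F, N, 3) coords as concatenated plain XYZ frames."""
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.shape[0]}\nframe\n")
            for x, y, z in frame:
                fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")
    return str(path)
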