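"""Build the packaged guest-molecule fixtures (.xyzq files).

Run once at development time; requires rdkit (not a runtime dependency of
the package).  Geometries come from distance-geometry embedding (ETKDGv3)
followed by MMFF94 relaxation; partial charges are PEOE (Gasteiger)
charges, symmetrised over topologically equivalent atoms and normalised so
they sum exactly to the formal net charge.  These charge sets stand in for
the unpublished DFT charges of the original adsorption study.

Usage: python tools/make_fixtures.py
"""

import math
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

OUT = Path(__file__).resolve().parents[1] / "src" / "ldhsim" / "data" / "fixtures"

SMILES = {
    # anionic azo dye, the study's model drug (sodium salt's anion)
    "methyl_orange": ("CN(C)c1ccc(cc1)/N=N/c1ccc(cc1)S(=O)(=O)[O-]", -1),
    # neutral tetracycline
    "tetracycline": (
        "C[C@@]1(O)c2cccc(O)c2C(=O)C2=C(O)[C@]3(O)C(=O)C(C(N)=O)=C(O)"
        "[C@@H](N(C)C)[C@@H]3C[C@@H]12",
        0,
    ),
    "ibuprofen": ("CC(C)Cc1ccc(cc1)C(C)C(=O)O", 0),
    # mannuronate-type monomer carrying two negative charges (carboxylate
    # plus one alkoxide), the 2- alginate repeat unit used in co-adsorption
    "alginate_monomer": ("O[C@@H]1O[C@H](C(=O)[O-])[C@@H](O)[C@H](O)[C@H]1[O-]", -2),
    "carbonate": ("C(=O)([O-])[O-]", -2),
    "water": ("O", 0),
}


def build(name, smiles, net):
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, name
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    assert AllChem.EmbedMolecule(mol, params) == 0, name
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    assert np.all(np.isfinite(q)), name
    # symmetrise over topologically equivalent atoms
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    for r in set(ranks):
        idx = [i for i, rr in enumerate(ranks) if rr == r]
        q[idx] = q[idx].mean()
    q += (net - q.sum()) / len(q)
    conf = mol.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    xyz -= xyz.mean(axis=0)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    formula = CalcMolFormula(mol)
    return elements, xyz, q, formula


def carbonate_flat(net=-2):
    """Ideal planar D3h carbonate (C-O 1.284 A); Gasteiger charges from the
    SMILES route, symmetrised."""
    els, _, q, formula = build("carbonate", SMILES["carbonate"][0], net)
    order = np.argsort([0 if e == "C" else 1 for e in els])
    q = q[order]
    els = [els[i] for i in order]
    r = 1.284
    xyz = np.array(
        [[0, 0, 0]]
        + [
            [r * math.cos(t), r * math.sin(t), 0.0]
            for t in (0, 2 * math.pi / 3, 4 * math.pi / 3)
        ]
    )
    return els, xyz, q, "CO3-2"


def water_ideal(net=0):
    """Gas-phase water geometry with Gasteiger charges."""
    els, _, q, _ = build("water", SMILES["water"][0], net)
    order = np.argsort([0 if e == "O" else 1 for e in els])
    els = [els[i] for i in order]
    q = q[order]
    r, theta = 0.9572, math.radians(104.52)
    xyz = np.array(
        [
            [0.0, 0.0, 0.0],
            [r, 0.0, 0.0],
            [r * math.cos(theta), r * math.sin(theta), 0.0],
        ]
    )
    xyz -= xyz.mean(axis=0)
    return els, xyz, q, "H2O"


def write(name, elements, xyz, q, formula, net):
    lines = [str(len(elements))]
    lines.append(
        f"name={name} formula={formula} net_charge={net} "
        "charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94"
    )
    for e, (x, y, z), qq in zip(elements, xyz, q):
        lines.append(f"{e} {x:.6f} {y:.6f} {z:.6f} {qq:.8f}")
    (OUT / f"{name}.xyzq").write_text("\n".join(lines) + "\n")
    print(f"{name:18s} {formula:14s} atoms={len(elements):3d} sum(q)={q.sum():+.6f}")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (smi, net) in SMILES.items():
        if name == "carbonate":
            write(name, *carbonate_flat(net), net)
        elif name == "water":
            write(name, *water_ideal(net), net)
        else:
            write(name, *build(name, smi, net), net)
    # monatomic species
    write("sodium", ["Na"], np.zeros((1, 3)), np.array([1.0]), "Na+1", 1)
    write("ghost", ["X"], np.zeros((1, 3)), np.array([0.0]), "X", 0)


if __name__ == "__main__":
    main()
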