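#!/usr/bin/env python
"""Optional validation against the deposited experimental fibril model (8R4A).

Requires either network access (the model is fetched from the PDB) or a local
copy passed with --model. Checks the structural facts the package should
reproduce on the real model:

  * 130 ordered residues per chain
  * exactly four disulfides: Cys6-Cys128, Cys30-Cys116, Cys65-Cys81, Cys77-Cys95
  * per-chain C-alpha z extent of about 19 A
  * a middle layer of a >= 19-layer symmetry expansion (twist -1.4 deg,
    rise 4.8 A) contacts 9 other layers, robust over cutoffs 4.0-5.0 A
  * three internal cavities in the central slab; the largest hydrophobic,
    the others polar
  * positions 54/57/64 solvent-exposed, position 56 buried

Usage:
    python scripts/validate_deposited.py [--model 8r4a.cif] [--out report.json]
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
import warnings
from pathlib import Path

from fibrilkit import (
    HelicalParams,
    apply_symmetry,
    classify_exposure,
    detect_disulfides,
    estimate_params,
    read_structure,
    z_extent,
)
from fibrilkit.cavities import cavity_polarity, detect_cavities
from fibrilkit.contacts import contact_count_vs_cutoff

PDB_URL = "https://files.rcsb.org/download/8R4A.cif"
EXPECTED_BRIDGES = {(6, 128), (30, 116), (65, 81), (77, 95)}


def fetch(dest: Path) -> Path:
    print(f"downloading {PDB_URL} ...")
    urllib.request.urlretrieve(PDB_URL, dest)
    return dest


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", type=Path, default=None, help="local 8R4A coordinate file")
    ap.add_argument("--out", type=Path, default=Path("deposited_validation.json"))
    args = ap.parse_args()

    path = args.model or fetch(Path("8r4a.cif"))
    model = read_structure(path)
    report: dict = {"source": str(path), "n_layers": model.n_layers}
    ok = True

    counts = [len(lay.residues) for lay in model.layers]
    report["residues_per_chain"] = counts
    ok &= all(c == 130 for c in counts)

    bonds = detect_disulfides(model)
    per_chain = {
        tuple(sorted((b.residue_a[1], b.residue_b[1])))
        for b in bonds
        if b.intra_chain and b.residue_a[0] == model.layers[0].chain_id
    }
    report["disulfides_layer0"] = sorted(per_chain)
    ok &= per_chain == EXPECTED_BRIDGES

    ze = z_extent(model.layers[0])
    report["z_extent_A"] = ze
    ok &= 17.0 <= ze <= 21.0

    params = model.helical or (
        estimate_params(model) if model.n_layers >= 2 else HelicalParams(-1.4, 4.8)
    )
    big = apply_symmetry(model.layers[0], HelicalParams(-1.4, 4.8), 21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts_by_cutoff = contact_count_vs_cutoff(big, 10, cutoffs=(4.0, 4.5, 5.0))
    report["contacting_layers_by_cutoff"] = counts_by_cutoff
    ok &= all(n == 9 for n in counts_by_cutoff.values())

    stack9 = apply_symmetry(model.layers[0], HelicalParams(-1.4, 4.8), 9)
    cavities = detect_cavities(stack9, rise=4.8)
    pol = [cavity_polarity(c, stack9) for c in cavities]
    report["n_cavities"] = len(cavities)
    report["cavity_polarity"] = pol
    ok &= len(cavities) == 3 and pol[0] == "hydrophobic" and pol[1:] == ["polar", "polar"]

    exposure = {}
    for pos, want in ((54, "exposed"), (57, "exposed"), (64, "exposed"), (56, "buried")):
        res = classify_exposure(stack9, pos)
        exposure[pos] = {"label": res.label, "relative_sasa": res.relative_sasa}
        ok &= res.label == want
    report["exposure"] = exposure

    report["all_checks_passed"] = bool(ok)
    args.out.write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
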