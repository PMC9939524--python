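"""Flag matched interface patches near known hotspot residues.

Hotspot residues dominate the binding energy of an interface and are
often conserved; a matched patch whose seed lies within 5 A of a hotspot
residue's heavy atoms is reported as a hotspot patch.  Here the "hotspot"
residues are simply the receptor residues closest to the partner.
"""

import numpy as np

import zernpatch as zp

spec = zp.ToyComplexSpec(geometry="slab", n_atoms=100, interface_gap=3.0, rng_seed=3)
rec, par = zp.build_parameterized_pair(spec)
ds = zp.compute_interface_descriptors(rec, par)
match = zp.match_patches(ds, ds)  # self-match: every patch is matched

# pick the two receptor residues that approach the partner most closely
partner_xyz = par.heavy_coords()
closest = {}
for atom, pos in zip(rec.heavy_atoms(), rec.heavy_coords()):
    d = np.linalg.norm(partner_xyz - pos, axis=1).min()
    key = (atom.chain_id, atom.residue_seq)
    closest[key] = min(d, closest.get(key, np.inf))
hotspots = sorted(closest, key=closest.get)[:2]
print("hotspot residues:", ", ".join(f"{c}{r}" for c, r in hotspots))

found = zp.identify_hotspot_patches(match, rec, hotspots, cutoff=5.0)
for rec_ in found:
    res = ", ".join(f"{c}{r}" for c, r in rec_["residues"])
    print(f"patch {rec_['patch_id']} is a hotspot patch (covers {res})")
print(
    f"\n{len(found)} of {len(match.pairs)} matched patches sit within 5 A "
    "of a hotspot residue."
)
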