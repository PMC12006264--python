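"""Hydrogen bonds and PAE-filtered interface contacts on a synthetic
two-chain complex.

Bonds are called from heavy-atom geometry (donor-acceptor distance and
the angle at the donor, with the relaxed tolerances); intra-chain bonds
need the partners more than five residues apart.  Contacts are residue
pairs of the two chains within 4 Å whose predicted aligned error is
below 5 Å in both directions.
"""

import tempfile
from pathlib import Path

from orthostruct.interactions import detect_hbonds, interface_contacts
from orthostruct.io_formats import read_pae, read_structure
from orthostruct.synthetic_data import SimConfig, make_comparison_bundle

cfg = SimConfig(
    seed=11, n_species=1, length=100, default_rate=0.0,
    indel_events_mean=0.0, insertion_events_mean=0.0,
    interface_contacts=(30, 60), hbond_sites=(30, 60),
)
with tempfile.TemporaryDirectory() as td:
    path, truth = make_comparison_bundle(cfg, td)
    chain_a, chain_b = read_structure(path / "sp1_complex.pdb")
    pae = read_pae(path / "sp1_pae.json")

    bonds = detect_hbonds([chain_a, chain_b])
    inter = [b for b in bonds if b.scope == "inter"]
    og = [b for b in inter if b.donor_atom == "OG" and b.acceptor_atom == "OG"]
    print(f"{len(bonds)} hydrogen bonds, {len(inter)} between chains")
    print("planted serine-serine bonds (donor residue, acceptor residue):",
          [(b.donor_residue + 1, b.acceptor_residue + 1) for b in og])

    contacts = interface_contacts(chain_a, chain_b, pae)
    print("PAE-confident contacts (chain A residue, chain B residue):",
          [(c.residue_a + 1, c.residue_b + 1) for c in contacts])
    print("planted contact positions:", truth.interface_contacts)
# only the planted pairs survive the PAE < 5 gate even though the two
# parallel chains are geometrically close along their whole length.
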