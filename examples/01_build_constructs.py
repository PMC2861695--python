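"""Build the twelve polypeptide models and print their region maps.

Three constructs (Q_n homopolymer, full exon1 XN1, and the polyP-deleted
XN1-ΔpolyP) at four glutamine repeat lengths. The printed lengths show the
arithmetic of the region map: XN1 carries 67 flanking residues
(17 + 11 + 17 + 10 + 12) and the ΔpolyP variant 46.
"""

from polyqmd import build_construct

for kind in ("QN", "XN1", "XN1_DP"):
    for n in (23, 36, 40, 47):
        m = build_construct(kind, n)
        regions = " ".join(f"{r.name}[{r.start}:{r.end}]" for r in m.regions)
        print(f"{m.name:>12}  {len(m):3d} residues  {regions}")

m = build_construct("XN1", 23)
print(f"\n{m.name} sequence ({len(m)} residues, the reference form):")
print(m.sequence)
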