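"""ATP cost primitives for the spore life cycle's fixed infrastructure.

Computes the closed-form direct (PD) and opportunity (PO) costs of
replicating the B. subtilis genome, building the asymmetric septum and
the full vegetative membrane, and remodeling the membrane during spore
revival.  These are the constants-only pieces of the ledger: they need no
expression data, only unit costs and geometry.
"""

from sporenergy import (
    GENOME_LENGTH_BP,
    membrane_cost,
    replication_cost,
    replication_cost_share,
    revival_membrane_cost,
    septum_cost,
)


def show(label: str, pair) -> None:
    print(f"{label:<28s} PD {pair.direct:10.3e}  PO {pair.opportunity:10.3e}  "
          f"PT {pair.total:10.3e} ATP")


rep = replication_cost(GENOME_LENGTH_BP)
show(f"genome replication ({GENOME_LENGTH_BP:,} bp)", rep)

# ~20% of genes are sporulation-related, spanning ~18% of the genome
show("  sporulation-gene share (18%)",
     replication_cost_share(0.18 * GENOME_LENGTH_BP, GENOME_LENGTH_BP))

n_lipid, mem = membrane_cost()
show(f"full membrane ({n_lipid:.3e} lipids)", mem)

n_sept, sept = septum_cost(1.0)
show(f"septum ({n_sept:.3e} lipids)", sept)

show("revival membrane (net)", revival_membrane_cost(mem))

print()
print("PT = PD + PO throughout; the membrane numbers count both leaflets of")
print("the bilayer at 0.65 nm^2 per lipid head with half the area occupied")
print("by protein.  Revival remakes 30% of the membrane and recycles 1/6 of")
print("the lipid cost, a net factor of 0.25 on the full-membrane cost.")
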