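# MM-GBSA per-term binding energies (kcal/mol, mean and SD over 200 snapshots)
# for the kinase-calmodulin complex in the ion-bound and ion-free states, as
# printed in the source publication's energy table.  These are INPUT data for
# the aggregation arithmetic, not values computed by this package.
# Note: the bound-state dE_vdW cell is corrupted in the published text; the
# value below (-190.76) is back-solved from the printed column total
# (-1650.34 + x + 1728.12 = -112.98).  The printed totals equal
# dE_ele + dE_vdW + dG_GB exactly, i.e. they exclude the dG_SA row.
state,term,mean,sd
bound,dE_ele,-1650.34,131.87
bound,dE_vdW,-190.76,12.27
bound,dG_SA,-29.32,1.52
bound,dG_GB,1728.12,124.22
bound,dG_binding,-112.98,20.63
unbound,dE_ele,-1840.20,141.32
unbound,dE_vdW,-191.96,14.10
unbound,dG_SA,-30.76,2.02
unbound,dG_GB,1945.76,134.08
unbound,dG_binding,-86.40,18.79
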