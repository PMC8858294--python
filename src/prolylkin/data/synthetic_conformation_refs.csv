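# Synthetic reference table for the four inter-domain conformational states.
# The (d, delta) centroids below are constructed values used to exercise and
# test the nearest-centroid classifier; they are NOT measurements of the
# deposited SlyD structures.
id,label,d_angstrom,delta_deg
synthetic_closed_1,closed,10.5,92.0
synthetic_closed_2,closed,11.2,95.5
synthetic_tight_1,tight,13.8,82.0
synthetic_tight_2,tight,14.6,85.0
synthetic_loose_1,loose,18.0,100.0
synthetic_loose_2,loose,19.5,104.0
synthetic_loose_3,loose,21.0,98.0
synthetic_open_1,open,26.0,118.0
synthetic_open_2,open,27.5,122.0
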