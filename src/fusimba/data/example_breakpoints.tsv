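# Illustrative recurrent-breakpoint table (NOT a validated clinical resource).
# Real deployments must supply their own table derived from curated fusion
# databases and in-house casework; only the ALK entry reflects the widely
# known hotspot after exon 19 upstream of the kinase domain.
gene_id	boundary_exon	retained_side
ALK	19	3prime
RET	11	3prime
ROS1	31	3prime
MET	13	3prime
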