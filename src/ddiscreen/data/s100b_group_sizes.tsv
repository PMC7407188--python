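# Reference virtual-proteome sizes for the three sample categories:
# total bacterial proteins attributed to the observed genera, number of genera,
# and proteins retained by the S100B partner-domain screen.
group	total_proteins	n_genera	n_interacting
CT	24306740	32	83008
CD	22066981	51	61086
UC	21402684	50	57344
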