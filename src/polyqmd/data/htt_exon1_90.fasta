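>htt_exon1_90 human huntingtin exon 1, first 90 residues (23-repeat polyQ form)
MATLEKLMKAFESLKSFQQQQQQQQQQQQQQQQQQQQQQQPPPPPPPPPPPQLPQPPPQA
QPLLPQPQPPPPPPPPPPGPAVAEEPLHRP
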