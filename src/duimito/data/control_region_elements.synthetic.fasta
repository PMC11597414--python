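>TAS synthetic stand-in for the termination-associated sequence element (replace with a curated sequence if available)
TACATAATTAAACAT
>CSB1 synthetic stand-in for conserved sequence block 1 (replace with a curated sequence if available)
TTATCACCCAAAGCTAAGATTCTAA
>mTF1 synthetic stand-in for a mitochondrial transcription-factor binding site (replace with a curated sequence if available)
ACACCCTCCTAGCCTTAACA
>mt3 synthetic stand-in for a mitochondrial transcription-factor binding site (replace with a curated sequence if available)
CACCATCCTCCGTGA
>mt4 synthetic stand-in for a mitochondrial transcription-factor binding site (replace with a curated sequence if available)
AGGACATCACGATGG
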