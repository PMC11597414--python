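# Gene-name synonym table used to normalize GenBank annotations to the
# canonical mitochondrial vocabulary (cox1..cox3, cob, nad1..nad6, nad4l,
# atp6, atp8, rrnS, rrnL, trnX with trnS1/trnS2 and trnL1/trnL2).
# Keys are matched case-insensitively after stripping spaces, hyphens and
# underscores.  Edit or extend freely: unknown names fall back to
# "unknown:<raw>" with a warning.
cox1: [cox1, coi, co1, coxi, "cytochrome c oxidase subunit 1", "cytochrome c oxidase subunit i", "cytochrome oxidase subunit 1"]
cox2: [cox2, coii, co2, coxii, "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit ii", "cytochrome oxidase subunit 2"]
cox3: [cox3, coiii, co3, coxiii, "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit iii", "cytochrome oxidase subunit 3"]
cob:  [cob, cytb, cob1, "cytochrome b", "cytochrome b apoenzyme"]
nad1: [nad1, nd1, "nadh dehydrogenase subunit 1"]
nad2: [nad2, nd2, "nadh dehydrogenase subunit 2"]
nad3: [nad3, nd3, "nadh dehydrogenase subunit 3"]
nad4: [nad4, nd4, "nadh dehydrogenase subunit 4"]
nad4l: [nad4l, nd4l, "nadh dehydrogenase subunit 4l"]
nad5: [nad5, nd5, "nadh dehydrogenase subunit 5"]
nad6: [nad6, nd6, "nadh dehydrogenase subunit 6"]
atp6: [atp6, atpase6, atpase 6, "atp synthase f0 subunit 6", "atp synthase subunit 6"]
atp8: [atp8, atpase8, atpase 8, "atp synthase f0 subunit 8", "atp synthase subunit 8"]
rrnS: [rrns, rrn12, 12s, "12s rrna", srrna, "s-rrna", "small subunit ribosomal rna", "12s ribosomal rna", ssu]
rrnL: [rrnl, rrn16, 16s, "16s rrna", lrrna, "l-rrna", "large subunit ribosomal rna", "16s ribosomal rna", lsu]
trnA: [trna-ala, trnala, trna_ala]
trnC: [trna-cys, trncys]
trnD: [trna-asp, trnasp]
trnE: [trna-glu, trnglu]
trnF: [trna-phe, trnphe]
trnG: [trna-gly, trngly]
trnH: [trna-his, trnhis]
trnI: [trna-ile, trnile]
trnK: [trna-lys, trnlys]
trnL1: [trnl1, "trna-leu(cun)", "trna-leu (cun)", trnleu1]
trnL2: [trnl2, "trna-leu(uur)", "trna-leu (uur)", "trna-leu(ttr)", trnleu2]
trnM: [trna-met, trnmet]
trnN: [trna-asn, trnasn]
trnP: [trna-pro, trnpro]
trnQ: [trna-gln, trngln]
trnR: [trna-arg, trnarg]
trnS1: [trns1, "trna-ser(agn)", "trna-ser (agn)", "trna-ser(agy)", trnser1]
trnS2: [trns2, "trna-ser(ucn)", "trna-ser (ucn)", "trna-ser(tcn)", trnser2]
trnT: [trna-thr, trnthr]
trnV: [trna-val, trnval]
trnW: [trna-trp, trntrp]
trnY: [trna-tyr, trntyr]
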