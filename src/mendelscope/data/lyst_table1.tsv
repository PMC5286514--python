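# LYST pathogenic allelic variants: published cDNA / protein HGVS pairs,
# transcribed verbatim (spacing and nonstandard dialects included).
dna_change	protein_change
c.118_119insG	p.Ala40GlyfsTer24
c.148C > T	p.Arg50Ter
c.925C > T	p.Arg309Ter
c.772T > C	p.Cys258Arg
c.1467delG	p.Glu489AspfsTer78
c.1540C > T	p.Arg514Ter
c.1902dupA	p.Ala635SerfsTer4
c.2413delG	p.Glu805AsnfsTer2
c.2454delA	p.Ala819Hisfs5
c.2623delT	p.Tyr875MetfsTer24
c.3073_3074 delAA	p.Asn1025GlnfsTer6
c.3085C > T	p.Gln1029Ter
c.3310C > T	p.Arg1104Ter
c.3434dupA	p.His1145GlnfsTer9
c.3622C > T	p.Gln1208Ter
c.3944_3945 insC	p.Thr1315fsTer1331
c.4052C > G	p.Ser1351Ter
c.4361 C > A	p.Ala1454Asp
c.4274delT	p.Leu1425TyrfsTer2
c.4688G > A	p.Arg1563His
c.5061T > A	p.Tyr1687Ter
c.5317delA	p.Arg1773 AspfsTer13
c.5506C > T	p.Arg1836Ter
c.5541_5542delAA	p.Gln1847fsTer1850
c.5996T > A	p.Val1999Asp
c.6078C > A	p.Tyr2026Ter
c.7060_7066del CTATTAG	p.Leu2354 MetfsTer16
c.7555delT	p.Tyr2519 IlefsTer10
c.7982C > G	p.Ser2661Ter
c.8281A > T	p.Arg2761Ter
c.8428G > A	p.Glu2810Lys
c.8583G > A	p.Trp2861Ter
c.9107_9162del56	p.Gly3036 GlufsTer16
c.9228_9229ins TTCTTTCAGT	p.Lys3077PhefsTer4
c.9590delA	p.Tyr3197LeufsTer62
c.9827_9832ATACAA	p.Asn3276_Thr3277del
c.9893delT	p.Phe3298Serfs7
c.10127A > G	p.Asn3376Ser
c.10395delA	p.Gly3466AlafsTer2
c.11102G > T	p.Glu3668Ter
c.11173G > A	p.Gly3725Arg
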