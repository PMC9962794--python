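gene,group,ligands,selectivity,evidence,basis
lgc-40,LGC-57,ACh|choline,anion,measured,
lgc-57,LGC-57,ACh|choline,anion,measured,
lgc-58,LGC-57,ACh|choline,anion,measured,
lgc-39,LGC-57,ACh|octopamine|tyramine|dopamine,anion,measured,
lgc-49,ACC,ACh,anion,measured,
lgc-46,ACC,ACh,anion,measured,
acc-1,ACC,ACh,anion,measured,
acc-2,ACC,ACh,anion,measured,
acr-16,nAChR,ACh,cation,measured,
unc-38,nAChR,ACh,cation,measured,
unc-29,nAChR,ACh,cation,measured,
unc-63,nAChR,ACh,cation,measured,
lev-1,nAChR,ACh,cation,measured,
lev-8,nAChR,ACh,cation,measured,
deg-3,nAChR,ACh|choline,cation,measured,
des-2,nAChR,ACh|choline,cation,measured,
unc-49,GABA,GABA,anion,measured,
gab-1,GABA,GABA,anion,measured,
lgc-37,GABA,GABA,anion,measured,
exp-1,GABA,GABA,cation,measured,
lgc-35,GABA,GABA,cation,measured,
glc-1,GluCl,glutamate,anion,measured,
glc-2,GluCl,glutamate,anion,measured,
avr-14,GluCl,glutamate,anion,measured,
avr-15,GluCl,glutamate,anion,measured,
glr-1,GluR,glutamate,cation,measured,
glr-2,GluR,glutamate,cation,measured,
nmr-1,GluR,glutamate,cation,measured,
mod-1,LGC-41,serotonin,anion,measured,
lgc-53,LGC-41,dopamine,cation,measured,
lgc-55,LGC-41,tyramine,anion,measured,
acc-4,ACC,ACh,anion,inferred,homology to measured group members: acc-1; acc-2; lgc-46; lgc-49 + PAR-motif call: anion
lgc-47,ACC,ACh,anion,inferred,homology to measured group members: acc-1; acc-2; lgc-46; lgc-49
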