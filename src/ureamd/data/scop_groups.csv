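symbol,pdb_code,molecule,group
a,1AGI,Angiogenin-1,all_alpha
b,1CHN,Chemotaxis protein CheY,all_alpha
c,1FVQ,Copper-transporting ATPase,all_alpha
d,1GND,Rab GDP dissociation inhibitor alpha,all_alpha
e,1KTE,Glutaredoxin-1 (Thioltransferase),all_alpha
f,1LIT,Lithostathine-1-alpha,all_alpha
g,1PDO,Mannose Permease - IIA domain,all_alpha
h,1SDF,Stromal cell-derived factor-1,all_alpha
i,1SUR,PAPS Reductase,all_alpha
j,2HVM,Hevamine,all_alpha
k,1BFG,Basic fibroblast growth factor,all_beta
l,1BJ7,Allergen Bos D2,all_beta
m,1CQY,Beta-amylase starch-binding domain,all_beta
n,1CSP,Cold shock protein B,all_beta
o,1CZT,Coagulation factor V C2 domain,all_beta
p,1J5D,Plastocyanin,all_beta
q,1KXA,Sindbis virus capsid protein,all_beta
r,1NSO,Protease,all_beta
s,1PHT,P13-kinase SH3 domain,all_beta
t,1BSN,F1-ATPase epsilon subunit,alpha_beta
u,1EMR,Leukemia Inhibitory Factor,alpha_beta
v,1IL6,Interleukin-6,alpha_beta
w,1JLI,Interleukin-3,alpha_beta
x,1K40,Focal adhesion kinase FAT domain,alpha_beta
y,1LKI,Leukemia Inhibitory Factor,alpha_beta
z,1OOI,Odorant binding protein LUSH,alpha_beta
alpha,1OPC,OMPR DNA-binding domain,alpha_beta
beta,1FAS,Fasciculin-1,small
gamma,1I6F,Alpha-like toxin CsEv5,small
delta,1SP2,SP1F2 zinc-finger DNA-binding domain,small
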