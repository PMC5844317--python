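let_name,chromosome,gene,protein_function,N,I,M,F
let-727,III,R02F2.7,Unknown,1,0,0,0
let-728,III,C23G10.8,Unknown,1,0,0,0
let-752,III,lin-13,Zinc-regulated transcription factor,1,0,0,0
let-798,III,wrm-1,Beta-catenin-like protein,1,0,0,0
let-342,V,pmt-2,Enzyme: phosphoethanolamine N-methyltransferase,1,0,0,0
let-428,V,K03B4.1,Unknown,1,0,0,0
let-455,V,Y45G5AM.9,Unknown,1,0,0,0
let-463,V,C04E6.11,Unknown,1,0,0,0
let-757/let-821,III,fbn-1,Extracellular matrix protein fibrillin,1,1,1,0
let-782,III,tag-189,Unknown,1,1,1,0
let-827,III,cee-1,Unknown,1,1,1,0
let-327,V,T08B1.1,Member of solute carriers family,1,1,1,0
let-344,V,sos-1,Son of sevenless homolog,1,1,1,0
let-348,V,rft-1,Member of solute carriers family; riboflavin transporter,1,1,1,0
let-423,V,mig-6,Extracellular matrix protein papilin/lacunin-like,1,1,1,0
let-440,V,ncx-2,Sodium/calcium exchanger,1,1,1,0
let-702,III,hmgr-1,Enzyme: 3-hydroxy-3-methylglutaryl-coenzyme A reductase,1,1,1,1
let-712,III,prp-8,mRNA splicing: pre-mRNA-processing-splicing factor,1,1,1,1
let-732,III,rpb-2,Enzyme: RNA polymerase II subunit,1,1,1,1
let-736,III,cdk-12,Enzyme: cyclin-dependent kinase,1,1,1,1
let-741,III,rars-1,Enzyme: arginyl aminoacyl tRNA synthetase,1,1,1,1
let-743,III,ZK686.2,Enzyme: ATP-dependent RNA helicase,1,1,1,1
let-747,III,algn-1,Enzyme: chitobiosyldiphosphodolichol beta-mannosyltransferase,1,1,1,1
let-753,III,C34E10.10,Ribosome-related protein: rRNA-processing protein,1,1,1,1
let-763,III,T08A11.2,mRNA splicing: splicing factor 3B subunit 1,1,1,1,1
let-764,III,byn-1,Bystin-related adhesion protein,1,1,1,1
let-771,III,rfl-1,Enzyme: ubiquitin activating enzyme,1,1,1,1
let-774,III,rps-3,Ribosome-related protein: small subunit ribosomal protein,1,1,1,1
let-784,III,gop-3,Sorting and assembly machinery complex component,1,1,1,1
let-786,III,unc-116,Kinesin-related motor protein,1,1,1,1
let-799,III,ddx-23,Enzyme: ATP-dependent RNA helicase,1,1,1,1
let-826,III,mrps-18C,Ribosome-related protein: mitochondrial small subunit ribosomal protein,1,1,1,1
let-829,III,atp-2,Enzyme: mitochondrial ATP synthase subunit,1,1,1,1
let-832,III,F09F7.4,Enzyme: 3-hydroxyisobutyryl-CoA hydrolase,1,1,1,1
let-972,III,hsp-110,Heat shock protein,1,1,1,1
let-326,V,rab-1,Enzyme: Rab family GTPase,1,1,1,1
let-331,V,prx-6,Peroxisomal biogenesis factor,1,1,1,1
let-332,V,C05C8.7,Enzyme: mannose phosphate isomerase,1,1,1,1
let-334,V,slc-17.8,Member of solute carriers family,1,1,1,1
let-335,V,C37C3.2,Translation initiation factor,1,1,1,1
let-338,V,rpac-40,Enzyme: RNA polymerase I/III shared subunit,1,1,1,1
let-343,V,cpsf-2,Cleavage and polyadenylation specificity factor,1,1,1,1
let-346,V,soap-1,HEAT repeat-containing protein,1,1,1,1
let-350,V,C37H5.5,Nucleolar complex protein-like DNA replication regulator,1,1,1,1
let-402,V,erfa-1,Translation termination factor,1,1,1,1
let-408,V,snap-1,Alpha-soluble NSF attachment protein,1,1,1,1
let-409,V,asns-1,Enzyme: asparagine synthase (glutamine-hydrolyzing),1,1,1,1
let-410,V,dlst-1,Enzyme: dihydrolipoamide S-succinyltransferase,1,1,1,1
let-411,V,xpo-1,Exportin-1 nuclear export receptor,1,1,1,1
let-415,V,hsp-6,Mitochondrial Hsp70-family chaperone,1,1,1,1
let-417,V,ceh-34,Homeobox protein,1,1,1,1
let-419,V,pqn-51,Transcription initiation factor IIA,1,1,1,1
let-420,V,adss-1,Enzyme: adenylosuccinate synthetase,1,1,1,1
let-422,V,hmgs-1,Enzyme: hydroxymethylglutaryl-CoA synthase,1,1,1,1
let-424,V,vars-1,Enzyme: valyl aminoacyl tRNA synthetase,1,1,1,1
let-439,V,M03F8.3,mRNA splicing: crooked neck pre-mRNA splicing factor,1,1,1,1
let-442,V,C05C8.2,Ribosome-related protein: small subunit processome component,1,1,1,1
let-447,V,egl-8,Enzyme: phospholipase C beta,1,1,1,1
let-459,V,hpo-18,Enzyme: ATP synthase,1,1,1,1
let-470,V,F11A3.2,Translation initiation factor,1,1,1,1
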