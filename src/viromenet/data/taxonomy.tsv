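taxon_id	name	rank	parent_id
root	root	root
ssdna	ssDNA viruses	group	root
dsdna	dsDNA viruses	group	root
bact	bacteria	group	root
arch	archaea	group	root
fungi	fungi	group	root
algae	unicellular algae	group	root
cyano	Cyanobacteria	order	bact
halob	Halobacteria	order	arch
caudo	Caudovirales	order	dsdna
micro	Microviridae	family	ssdna
gokus	Gokushovirinae	subfamily	micro
gokuv	Gokushovirus	genus	gokus
gokuv_s1	Gokushovirus sp. NS1	species	gokuv
gokuv_s2	Gokushovirus sp. NS2	species	gokuv
gokuv_s3	Gokushovirus sp. NS3	species	gokuv
circo	Circoviridae	family	ssdna
circv	Circovirus	genus	circo
circv_s1	Circovirus sp. NS1	species	circv
circv_s2	Circovirus sp. NS2	species	circv
inovi	Inoviridae	family	ssdna
inov	Inovirus	genus	inovi
inov_s1	Inovirus sp. NS1	species	inov
gemin	Geminiviridae	family	ssdna
mastr	Mastrevirus	genus	gemin
mastr_s1	Mastrevirus sp. NS1	species	mastr
umssv_s1	uncultured marine ssDNA virus 1	species	ssdna
umssv_s2	uncultured marine ssDNA virus 2	species	ssdna
podo	Podoviridae	family	caudo
podov	Podovirus	genus	podo
podov_s1	Podovirus sp. NS1	species	podov
podov_s2	Podovirus sp. NS2	species	podov
sipho	Siphoviridae	family	caudo
siphv	Siphovirus	genus	sipho
siphv_s1	Siphovirus sp. NS1	species	siphv
siphv_s2	Siphovirus sp. NS2	species	siphv
myovi	Myoviridae	family	caudo
myov	Myovirus	genus	myovi
myov_s1	Myovirus sp. NS1	species	myov
myov_s2	Myovirus sp. NS2	species	myov
salte	Salterprovirus	genus	dsdna
salte_s1	His1-like salterprovirus NS1	species	salte
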