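# Common botanical author abbreviations, one per line: abbreviation<TAB>expansion
# A small built-in sample; extendable via configuration.
L.	Linnaeus
DC.	de Candolle
A.DC.	Alphonse de Candolle
Benth.	Bentham
Hook.	Hooker
Hook.f.	Hooker filius
Kunth	Kunth
Steud.	Steudel
Nees	Nees
Mart.	Martius
Willd.	Willdenow
Lam.	Lamarck
Juss.	Jussieu
Cav.	Cavanilles
Desf.	Desfontaines
Thunb.	Thunberg
Sw.	Swartz
Vahl	Vahl
R.Br.	Robert Brown
A.Gray	Asa Gray
Torr.	Torrey
Nutt.	Nuttall
Michx.	Michaux
Pursh	Pursh
Raf.	Rafinesque
Spreng.	Sprengel
Schltdl.	Schlechtendal
Cham.	Chamisso
Kuntze	Kuntze
Engl.	Engler
Baker	Baker
Oliv.	Oliver
Hemsl.	Hemsley
Standl.	Standley
Urb.	Urban
Griseb.	Grisebach
Poir.	Poiret
Pers.	Persoon
Roxb.	Roxburgh
Wall.	Wallich
Miq.	Miquel
Blume	Blume
Ruiz	Ruiz
Pav.	Pavon
Aubl.	Aublet
Jacq.	Jacquin
Mill.	Miller
Moench	Moench
Scop.	Scopoli
Gaertn.	Gaertner
Salisb.	Salisbury
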