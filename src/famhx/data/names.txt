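# Common first names and surnames removed during sentence cleaning.
james
john
robert
michael
william
david
richard
joseph
thomas
charles
christopher
daniel
matthew
anthony
mark
donald
steven
paul
andrew
joshua
kenneth
kevin
brian
george
timothy
ronald
edward
jason
jeffrey
ryan
jacob
gary
nicholas
eric
jonathan
stephen
larry
justin
scott
brandon
benjamin
samuel
gregory
frank
alexander
raymond
patrick
jack
dennis
jerry
peter
saul
walter
henry
mary
patricia
jennifer
linda
elizabeth
barbara
susan
jessica
sarah
karen
lisa
nancy
betty
margaret
sandra
ashley
kimberly
emily
donna
michelle
carol
amanda
dorothy
melissa
deborah
stephanie
rebecca
sharon
laura
cynthia
kathleen
amy
angela
shirley
anna
ruth
brenda
pamela
nicole
katherine
virginia
catherine
christine
samantha
debra
janet
rachel
carolyn
emma
maria
heather
diane
julie
joyce
victoria
smith
johnson
williams
brown
jones
garcia
miller
davis
wilson
anderson
taylor
thompson
moore
martin
lee
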