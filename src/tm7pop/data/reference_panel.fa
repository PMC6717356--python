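>v1r1|v1r
MPTYDDHSYSEGYKKKRHDDQNIFMAAMIFMFFIFFFMIMFAMLMEGNHHGHKHDTDHTVLVAMIAVILVAFAVVMFMAVALDKKYSGDNQHPKKYPDMLIILFMFLLMLLVFVMMIMIVVRYDHYGDRNGKHHQRLLMVLFILALFFIVVIFMLAIAAEQSNQDRQKKYPKGRKRLVLIVMMFLLMILALIIAFFLVMEHQERQQRPDNSYDVLVVAAMVFFAFFVIAVVMFIFVKNEDNNYPTKGGYQKRMMMMFLLAMIVAIMFLIAAFIMAPEKSPSSNSYGKGTKYHQRPTNGNRSYK
>v1r2|v1r
MPRYDDHSYSEGYKKPRHDDQNIFMAAMIFMFFAFFFVIMFAMLMGGQHHGHKHDTYQDVLVAMIAVILAAFAMVVFMAVALDKKYSGENDHPKKYPDMLIILFMFLLMLMAFFMMLMAVVRYDHYGDTNGKRHYRFLMFLFAAALFFVAVIFMLVIAAEQENQDPQKKYEKNPKRLVLIMMFFLLVILILIIAFFLVMEHQERQHRRDNSYDVLVVAAMVAFAFFVIFVMMIIFVKNESNNYPTKDGYHKRMMALILFMMIVAIMFLFIAFIFIPQKSPTENSYGRGTKYDRRPTNGNRTYN
>v1r3|v1r
MHQYDNHSYSEGYKKNRHDDQNIFMAAMIFMFFAFFFVIMFAMLLEGSHHGHKHDTDHRVLVAMIAVIFAVFAVVLFMAVALDKKYSGENDHPKKYPDMLIILFMILLMLLVFAMMLMVFVRYDHYGDTNGGRHYRLLMFLFILALFFIAVIFMLVIIMEQSNQDPQKKYEKGRERLVLMMMFFLLMILALIIAFFLVMYHQERQTRPTNEYDVLVVAAMVAFAFFVIVVLMFIFVKNESNNYPTPDGYQKQMMMMFLFAMFVAIMFLFAVFIAIPEKSPSSNSYGRGTRYEQRPTNGQTSHN
>v1r4|v1r
MPRYDDHSYSEGYKKNRHDDQNIFMAAMIAMFFAFFFLIMFAMLMSGNHHGHKHDTDHRVLVAMIVVILAAFAVVVFMIVALDKKYNGENDHPKKYPDMIIILFMFLLMLLVFFMMLMAVVRYDHYGDTNGKRHYRFLMFLVILALFFIAMIFMLFIAAEQSNQDPQKPYEKTRKRLVLIMMMFLLAFLALIIAFFLVMEDQEYQQRPDNSYDVLVVAAMVAFMFVVIVVLMFIFVKNESNNYPTKDGYQKRMMMMFLFAMIVAFMFLFAAIFFIHEKSPSSNSYGRGTKYDQRPHNGNRSYN
>v1r5|v1r
MPRHDDHSYSEGYKKNRHDDQNIFMAAAIVMFFIFFFVLMFAMLATGNHHGHKHDTDDRVLAAMIMVILAAFAVVVFMAVALDKKHSGQNDHPKKYPDMLIALFMFLLMLLVFFMMLMAVIQYDHYGDTNGKRHYRLLMFLFILALFLIIVIFMLVIAAEQSNQDSQKKYEKGRKRLFLIMMFFLLVILVLIIAFFLVMEDQERQQRPDNSKDVLVVAAFVAFAFFVIVVLMIIFFKNESNNYPTKDGYQKRMMMMFLFMMIVAIMFLFAAFIFIPEKSPSSNSYGRGTKYYQRPTNGNTEHN
>v1r6|v1r
MPRYDDHSYSEGYKKTRHDDQNIFMIAMIFMVFAFFFIIMFALLMEGNGHGDKHDTDHRVLVAMIAVILIAFFVVVFMAVALDKKYSGEHDHNEKYPDMLIILFMFLLALLVFFMMVMAAVRYDHYGYTNGKTHYPLLMFLFILALFVIAVIMMLVIAAEQSNQKEQKKYEKGTKRLVLIMMFFLLAILALIIAFFLVMEHQERQQPPDNSYDVLVVAAMVAFVFFVIFVLMFIFVKNESNNYPNKDGEQKRMMMIFLFAMIVAIMMLFAAFIFIPNKSPSSNSYGRGTKYDQRPTNGNRSYN
>v1r7|v1r
MPRYDDHSYSEGHKKNRHDDQNIFMAAMIFMFFAFFFVFMFAMLMEGNHHGHKHDTDHRVLVAMIAAILAAFAVVVFMAVALRKKYSRENDKPKKYYNMLIILFMFLLVLLVFFMMLLAIVDHDHYGDTTGKRHYRLVMFVVILALFFIAVIFMLVIAAEQSNQDPQKKYEKGRKRLVLIMMFFLLVFLALIIAFFLVMEHQERQQRPDNYYDILVVAMMAAFAFFVAVVLMFIFAKNESNNYPNKDEYQKRMMMMFLFALIVAIMFLFAAFIAIPEKSPSSNSPGRGTKYDQRPTNGNRSYN
>v1r8|v1r
MPRYDDHSYSEGYKKNRHDDENIFMAAMIFMFFAFFFVIMFAMLMEGNHHGHKHDTDHHVLVAMIAVILAAFAVVVFMFVALDKKYSGENDHPKKYPDMLIILFMFLLMLLVFFMMLMAVVREDHYGDTNGKPHYRLLMFLFILALFFIAVIFMLVIAAEQSNQDPQKKYEKGRKNLVLIMMFFLLVILAAIIAFFLVMEHQERQQRPDNSYDVLVVAAMVAFAFFVIVVLMFFFIKNESNSYPTKDGSQKRMMMMFLFAMIVVIMFLFAAFAFIPEKSPSSNSYGRGTKYDQRPTNGNRSYN
>gpcrdecoy1|decoy
MNKYERGKDNTKRGHDYNNTNTRDPQESSEFAIMFFAIFMVFVLLAMMLIAMEQEPPTPQKKPDRRDLALFIIAAIFAVIAVVMMFVVMRYTDGTKKQEEHDRALALFAAAMVAFAVFLVAMAIMKSPSGQDQHNPEKTTGDLVMVVFFVFLIFAAMFMAALMFRRYSDNRGRPTNSRSDFMMIAMAALVLAVFIIMFMLMAKHDKNHSNPNSPREPMLFALFLAVLFMVAVAIMVVFAKETQKRKPNHYPNKALILMIILFAFFLLMIVLIAAITETRGQTKDYDPQGTQQTYRDYKNDNKHYKNRSPT
>gpcrdecoy2|decoy
MNKSERGKYNTHRHHDYNKTRTRNPQESSEFFIAFFIFFMVFVLLAMILIALEQEPDTPQKSPDPRDLFMFIIAAIFAVIAVFMAFVVMRPTQGTTKQEEHGRALILVAMAMVALAVFLVAAAMMKPPSGQDQHNPEKQTGDLVMVVFFVFLIFAAMFMIALMFRRYSDNRSRPTNSRSDFMLIAMFALIMAVFIIMVMVIAKHDKNHSNPNSPRERMLAALFLFVLFMILLALMLIFAKETQTGKPDHYPNKILILMIIFFAFFLIMIVLIAAITETRGQTKDYEPQGTQQTYRDYKNNNYHYKSRGPT
>gpcrdecoy3|decoy
MNKDERGKYNTKRHHDYNNTNTRNPQESSEFAIMFFAFFFVFVLLAMMLIALEQEPPGPQKKPDRRDFAMFIIAAIFAVIAVFMMFVVMRPTDGTTKQEHHGRALALMAMAMVALAVFLVAAAAMKSPSGQDQHNPEQRTGDLVMVVFFFFLIMAAMFMAMLMFRRYSDNRERPTNSRSDFMLIAMFALVMAVFIIMVMLVAKHDKNHSNPNSPRERMLAALFLFVLFMILVAIMLIFAKETQTRKPDHYPNKMLILMIILFAFFLLMIVLIAAITYTRGYTKDYKPEGGQQTYRDYKNDNYHYKSRGPG
>gpcrdecoy4|decoy
MNKYERGKYNTKRHHRYNNTNTRNPQESSEFALMFFAFFMVFVLAAMMLIALEQEPPSPQKKPDRRDMAMFIIFAIFLIIAVFMAFVVMRPTDGTTKQEEHGRALALFAMAMVAIFVFLVAFAMLKKPSGQDQHNPEQQTGDLVMVVFFMMLIFLAMFMAALMIRRYSDNRSRPTHSRSDFMLIAVVALVMMVFIIMVMAIAKHDHNTSNPNKPRERMLAALFLFVLFMILVAIMLIFAKETQTRKPDHYPNKALILIIILFALFLLMILLFAAIREDRGQTKDDKPQGTQQTYRDYQNDNYDYKSRGPT
>gpcrdecoy5|decoy
MNKYERGKYNTKRHRDYNNTNTRNTQESSEFAFMFFAFFMVFVALAMMLIALEQEPPTPQKKPDRRDLAMFIIAAFFAVIAVLMAFVVMRPTDGTTKQEEHGRALALFAMAMFAIAVFLVAIAAMESTSGNDQHNPEQTTGDMVMVVFFVFLIFAAMFMAVLMFRRYSDNRSRPTKSRSDFMLIAMFALVMIVFIIMVMLFAKHDKNHSNPNSPRERMLAALFLFVLFMILVAIMLIFAKETQTRKPDRYPKKALILMIILFVFFLLMIVLIMAVTESRGQTKDYTPQGTQQTYRDHKNDNYRYKSRGPH
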