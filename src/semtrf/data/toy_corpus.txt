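the boy walked down the road to the river.
the girl walked down the road to the market.
the old man sat by the river and watched the water.
the old woman sat by the fire and told a story.
every morning the boy carried water from the river to the house.
every morning the girl carried bread from the market to the house.
the dog ran across the field and barked at the birds.
the cat sat on the wall and watched the dog.
the boy and the girl played by the river after school.
the teacher told the children a story about the old town.
the children listened to the story and asked many questions.
the farmer worked in the field from morning to night.
the farmer carried the corn to the market in a cart.
the horse pulled the cart down the long road.
the rain fell on the field and the river rose.
the river rose and the water covered the road.
the boy could not walk to school because of the water.
the girl helped the old woman carry wood for the fire.
the fire kept the house warm through the long winter.
in the winter the children played in the snow by the house.
in the summer the children swam in the river near the bridge.
the bridge over the river was old and made of stone.
the old stone bridge was the pride of the town.
the people of the town met at the market every week.
the baker sold bread at the market every morning.
the baker gave the boy a small loaf of bread.
the boy gave the dog a piece of the bread.
the dog followed the boy all the way home.
the mother called the children home for dinner.
the father came home from the field at night.
after dinner the family sat by the fire and talked.
the grandfather told a story about the great storm.
the great storm had broken the old bridge long ago.
the people built a new bridge after the storm.
the new bridge was strong and wide.
the teacher walked across the bridge to the school.
the school stood on the hill above the town.
from the hill the children could see the whole valley.
the valley was green in spring and gold in autumn.
in autumn the farmer gathered the corn from the field.
the birds flew south over the valley in autumn.
the boy watched the birds from the top of the hill.
the girl drew a picture of the birds and the river.
the teacher hung the picture on the wall of the school.
the children sang a song about the river and the hills.
the song was old and everyone in the town knew it.
the old man hummed the song as he walked to the market.
the market was full of people on the day of the fair.
at the fair the children ate sweet cakes and played games.
the baker baked a great cake for the fair.
the mayor of the town opened the fair with a speech.
the speech was long and the children grew restless.
after the speech the music began and the people danced.
the girl danced with her mother by the fountain.
the fountain in the square was built of white stone.
the water in the fountain sparkled in the sun.
the sun set behind the hills and the sky turned red.
at night the stars shone over the quiet town.
the boy looked at the stars from his window.
the cat slept at the foot of the boy's bed.
in the morning the birds sang in the garden.
the garden behind the house was full of flowers.
the mother picked flowers from the garden for the table.
the father built a small boat for the boy.
the boy sailed the small boat on the river.
the wind pushed the boat across the water.
the dog swam after the boat and barked.
the girl laughed at the dog from the bank of the river.
the bank of the river was soft with green grass.
the children lay on the grass and watched the clouds.
the clouds moved slowly over the valley.
one cloud looked like a horse and one like a fish.
the fish in the river jumped in the evening light.
the old man caught a fish with a long pole.
the old woman cooked the fish over the fire.
the family ate the fish with bread from the market.
after the meal the grandfather lit his pipe and smiled.
the boy asked the grandfather about the old days.
in the old days the road to the town was only a path.
the path ran through the forest and over the hill.
the forest was dark and full of tall trees.
the children did not go into the forest alone.
the woodcutter worked in the forest with his axe.
the woodcutter brought wood to the town before winter.
the people stored the wood for the cold months.
the cold months passed slowly in the little town.
when spring came the ice on the river broke.
the river carried the ice past the bridge to the sea.
the sea was far away beyond the hills.
the boy dreamed of sailing to the sea one day.
the girl dreamed of teaching at the school one day.
the teacher said that dreams need patient work.
the children worked at their letters every day.
the boy wrote his name on the slate with chalk.
the girl read her book by the window in the evening.
the book told of ships and storms and far lands.
the lamp burned late while the girl read her book.
the mother smiled and let the lamp burn a little longer.
the town slept under the quiet stars.
the river ran past the town through the night.
the morning came with the sound of the baker's cart.
the cart rolled over the stone bridge into the square.
the square filled with people and the day began.
the day began with bread and ended with stories.
stories held the little town together like the bridge held the road.
the boy grew tall and strong by the river.
the girl grew wise and kind in the school.
years passed and the children told the old stories to their own children.
the old stories never lost their way home.
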